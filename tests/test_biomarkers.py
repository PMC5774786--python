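"""Linear gains, group statistics and the Fisher discriminant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import eegpdm as eg
from eegpdm.biomarkers import (
    classify,
    confusion_metrics,
    feature_pair_search,
    linear_gain,
    shapiro_wilk,
    state_contrast_test,
    train_linear_discriminator,
)


class TestLinearGain:
    def test_linear_anf_gain_is_a1(self, rng):
        u = rng.standard_normal(500)
        assert linear_gain([2.5, 0.0, 0.0], u) == pytest.approx(2.5, abs=1e-12)

    def test_cubic_gain_matches_polyfit_oracle(self, rng):
        u = rng.standard_normal(5000)
        u -= u.mean()
        f = u**3
        expected = np.polyfit(u, f, 1)[0]
        assert linear_gain([0.0, 0.0, 1.0], u) == pytest.approx(expected, rel=1e-10)
        # for near-standard-normal u the slope approaches m4/m2 ~ 3
        assert linear_gain([0.0, 0.0, 1.0], u) == pytest.approx(3.0, rel=0.15)

    def test_even_anf_on_symmetric_samples_has_near_zero_gain(self, rng):
        half = rng.standard_normal(2000)
        u = np.concatenate([half, -half])  # exactly symmetric about 0
        assert abs(linear_gain([0.0, 1.0, 0.0], u)) < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_gain([1.0, 0.0, 0.0], np.ones(100))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            linear_gain([1.0], rng.standard_normal(5))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=-5, max_value=5).filter(lambda c: abs(c) > 1e-3),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_gain_scales_linearly_with_anf_scaling(scale, seed):
    u = np.random.default_rng(seed).standard_normal(200)
    base = linear_gain([1.0, 0.5, -0.2], u)
    scaled = linear_gain([scale * 1.0, scale * 0.5, scale * -0.2], u)
    assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-12)


class TestShapiroWilk:
    def test_calibration_on_normal_draws(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).standard_normal(50)) > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_power_against_exponential(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).exponential(size=50)) < 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))


class TestStateContrast:
    def test_identical_pairs_report_p_one(self):
        x = np.arange(10, dtype=float)
        assert state_contrast_test(x, x.copy(), "paired") == 1.0

    def test_constant_shift_highly_significant(self, rng):
        base = rng.standard_normal(12)
        shifted = base + 5.0 + 0.01 * rng.standard_normal(12)
        p = state_contrast_test(shifted, base, "paired")
        # oracle: one-sample t on the differences
        d = shifted - base
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_oracle = 2 * stats.t.sf(abs(t), d.size - 1)
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert p < 1e-3

    def test_welch_mode_matches_explicit_formula(self, rng):
        a = rng.standard_normal(15) + 0.3
        b = 2.0 * rng.standard_normal(10)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert state_contrast_test(a, b, "welch") == pytest.approx(p_oracle, rel=1e-9)

    def test_type_I_rate_on_null_gains(self):
        # paired test on two draws from one law rejects ~5% of the time
        rejections = 0
        for s in range(200):
            g = np.random.default_rng(s)
            rejections += state_contrast_test(
                g.standard_normal(10), g.standard_normal(10), "paired"
            ) < 0.05
        assert 2 <= rejections <= 25  # binomial(200, 0.05) comfortably

    def test_mismatched_paired_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            state_contrast_test(rng.standard_normal(5), rng.standard_normal(4))


class TestFisherDiscriminant:
    def test_separable_classes_give_zero_errors(self, rng):
        X = np.vstack([
            rng.standard_normal((20, 2)) * 0.1 + [3, 0],
            rng.standard_normal((20, 2)) * 0.1 + [-3, 0],
        ])
        y = np.array([True] * 20 + [False] * 20)
        res = train_linear_discriminator(X, y)
        assert res.FN == 0 and res.FP == 0
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_permuted_labels_give_chance_accuracy(self):
        accs = []
        for s in range(30):
            g = np.random.default_rng(s)
            X = np.vstack([
                g.standard_normal((10, 2)) + [2, 0],
                g.standard_normal((10, 2)) - [2, 0],
            ])
            y = g.permutation([True] * 10 + [False] * 10)
            res = train_linear_discriminator(X, y)
            # held-out half: evaluate on a fresh permuted draw
            Xh = np.vstack([
                g.standard_normal((10, 2)) + [2, 0],
                g.standard_normal((10, 2)) - [2, 0],
            ])
            yh = g.permutation([True] * 10 + [False] * 10)
            accs.append(np.mean(classify(res, Xh) == yh))
        assert 0.35 < np.mean(accs) < 0.65

    def test_confusion_invariant_under_axis_rescaling(self, rng):
        X = np.vstack([
            rng.standard_normal((15, 2)) + [1.5, -0.5],
            rng.standard_normal((15, 2)) - [1.5, -0.5],
        ])
        y = np.array([True] * 15 + [False] * 15)
        r1 = train_linear_discriminator(X, y)
        X2 = X * [250.0, 0.004] + [7.0, -3.0]
        r2 = train_linear_discriminator(X2, y)
        assert (r1.TP, r1.FN, r1.TN, r1.FP) == (r2.TP, r2.FN, r2.TN, r2.FP)

    def test_agrees_with_sklearn_lda_direction(self, rng):
        # independent implementation check: sklearn's LDA with equal priors
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = np.vstack([
            rng.standard_normal((25, 2)) + [1, 0.5],
            rng.standard_normal((25, 2)) - [1, 0.5],
        ])
        y = np.array([1] * 25 + [0] * 25)
        ours = train_linear_discriminator(X, y.astype(bool))
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        cos = ours.weights @ sk.coef_[0] / (
            np.linalg.norm(ours.weights) * np.linalg.norm(sk.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-6)
        assert np.array_equal(classify(ours, X), sk.predict(X).astype(bool))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_linear_discriminator(
                rng.standard_normal((6, 2)), np.ones(6, dtype=bool)
            )


class TestConfusionMetrics:
    def test_published_test_set_arithmetic(self):
        # 188 ictal test epochs with 8 false negatives -> 95.7% sensitivity;
        # 10 false positives at the implied interictal count -> 95.2%
        sens, spec = confusion_metrics(TP=180, FN=8, TN=198, FP=10)
        assert sens == 95.7
        assert spec == 95.2

    def test_perfect_and_degenerate_cases(self):
        assert confusion_metrics(10, 0, 10, 0) == (100.0, 100.0)
        assert confusion_metrics(0, 5, 3, 0)[0] == 0.0

    @pytest.mark.parametrize("counts", [(0, 0, 5, 5), (5, 5, 0, 0), (-1, 2, 3, 4)])
    def test_invalid_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            confusion_metrics(*counts)


class TestGainTableAndPairSearch:
    def test_designated_pair_separates_best(self, trained):
        ranked = feature_pair_search(trained.gains)
        best_pairs, best_err = ranked[0][:2], ranked[0][2]
        assert best_err == 0
        assert (("input2", 2), ("input2", 4)) in [
            tuple(sorted(r[:2])) for r in ranked if r[2] == 0
        ]

    def test_gain_table_schema(self, trained):
        g = trained.gains
        assert set(g.columns) == {"subject_id", "state", "input", "branch", "gain"}
        assert len(g) == 20 * 2 * 5  # epochs x inputs x branches
        assert g.gain.notna().all()
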