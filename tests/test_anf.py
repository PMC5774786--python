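"""ANF fitting, cross-term screening and model selection."""

import numpy as np
import pytest

import eegpdm as eg
from eegpdm.anf import (
    fit_anfs,
    model_selection,
    pdm_outputs,
    predict_pdm_model,
    select_cross_terms,
)
from eegpdm.synthetic import band_limited_noise


@pytest.fixture(scope="module")
def ortho_pdms():
    gt = eg.make_ground_truth_laguerre(M=32, H=3, seed=5)
    return gt.pdms


@pytest.fixture(scope="module")
def branch_outputs(ortho_pdms):
    rng = np.random.default_rng(17)
    x1 = band_limited_noise(3000, 256.0, 40.0, rng)
    x2 = band_limited_noise(3000, 256.0, 40.0, rng)
    return pdm_outputs(ortho_pdms[0], x1), pdm_outputs(ortho_pdms[1], x2)


class TestPdmOutputs:
    def test_impulse_reproduces_pdms(self, ortho_pdms):
        x = np.zeros(64)
        x[0] = 1.0
        u = pdm_outputs(ortho_pdms[0], x)
        np.testing.assert_allclose(u[:32], ortho_pdms[0], atol=1e-14)

    def test_reversed_pdm_correlation_peak(self, ortho_pdms):
        G = ortho_pdms[0]
        M = G.shape[0]
        x = G[::-1, 1].copy()  # branch 2 reversed in time
        u = pdm_outputs(G, x)
        assert u[M - 1, 1] == pytest.approx(1.0, abs=1e-10)

    def test_linearity(self, ortho_pdms, rng):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(
            pdm_outputs(ortho_pdms[0], 3.0 * x),
            3.0 * pdm_outputs(ortho_pdms[0], x),
            atol=1e-12,
        )


class TestCrossTermScreen:
    def test_perfectly_correlated_pair_selected(self, branch_outputs):
        u1, u2 = branch_outputs
        O = u1[:, 0] * u2[:, 0]
        sel = select_cross_terms(u1, u2, O, seed=3)
        assert (1, 1) in sel

    def test_independent_output_rarely_selects(self, branch_outputs):
        u1, u2 = branch_outputs
        O = np.random.default_rng(99).standard_normal(u1.shape[0])
        sel = select_cross_terms(u1, u2, O, n_surrogates=200, seed=4)
        assert len(sel) <= 1  # 9 candidates at the 99% level

    def test_no_interaction_cohort_selects_few(self, inspan_gt):
        # no true cross-pairs: the screen returns small sets.  The rate sits
        # above the pure-null 1% because the output depends on the branch
        # outputs through the ANFs (higher-order dependence the shift
        # surrogates do not null), but stays far from systematic selection.
        counts = []
        for seed in (21, 22, 23, 24):
            ep = eg.simulate_epoch(inspan_gt, "interictal", seed=seed)
            u1 = pdm_outputs(inspan_gt.pdms[0], ep.input1)
            u2 = pdm_outputs(inspan_gt.pdms[1], ep.input2)
            counts.append(len(select_cross_terms(u1, u2, ep.output, seed=seed)))
        assert np.mean(counts) <= 0.2 * 25
        assert min(counts) <= 2

    def test_invalid_level_rejected(self, branch_outputs):
        u1, u2 = branch_outputs
        with pytest.raises(ValueError):
            select_cross_terms(u1, u2, u1[:, 0], level=0.5)


class TestFitANFs:
    def test_recovers_known_cubic_coefficients(self, branch_outputs):
        u1, u2 = branch_outputs
        rng = np.random.default_rng(1)
        a = rng.standard_normal((2, 3, 3))
        O = 0.7 * np.ones(u1.shape[0])
        for idx, u in ((0, u1), (1, u2)):
            for h in range(3):
                for p in range(3):
                    O = O + a[idx, h, p] * u[:, h] ** (p + 1)
        model = fit_anfs(u1, u2, [], O, order=3)
        np.testing.assert_allclose(model.anf_coeffs, a, rtol=1e-6, atol=1e-8)
        assert model.intercept == pytest.approx(0.7, abs=1e-8)
        assert model.nmse < 1e-12

    def test_single_linear_branch(self, branch_outputs):
        u1, u2 = branch_outputs
        model = fit_anfs(u1, u2, [], 2.0 * u1[:, 0], order=3)
        assert model.anf_coeffs[0, 0, 0] == pytest.approx(2.0, abs=1e-6)
        others = model.anf_coeffs.copy()
        others[0, 0, 0] = 0.0
        assert np.abs(others).max() < 1e-6

    def test_cross_term_coefficient_estimated(self, branch_outputs):
        u1, u2 = branch_outputs
        O = u1[:, 1] + 1.5 * u1[:, 0] * u2[:, 2]
        model = fit_anfs(u1, u2, [(1, 3)], O, order=1)
        assert model.cross_terms == [(1, 3, pytest.approx(1.5, abs=1e-8))]

    def test_nesting_never_increases_training_nmse(self, branch_outputs):
        u1, u2 = branch_outputs
        rng = np.random.default_rng(2)
        O = np.tanh(u1[:, 0]) + u2[:, 1] ** 2 + 0.1 * rng.standard_normal(u1.shape[0])
        errs = [fit_anfs(u1, u2, [], O, order=p).nmse for p in (1, 2, 3)]
        assert errs[0] >= errs[1] >= errs[2]
        # adding cross terms also never hurts
        assert fit_anfs(u1, u2, [(1, 1)], O, order=3).nmse <= errs[2] + 1e-12

    def test_sample_budget_precondition(self, branch_outputs):
        u1, u2 = branch_outputs
        with pytest.raises(ValueError):
            fit_anfs(u1[:50], u2[:50], [], np.zeros(50), order=3)

    def test_odd_symmetric_truth_recovers_negligible_even_part(self):
        # generative ANFs with a2 = 0 at 20 dB SNR: fitted quadratic
        # coefficients stay below 5% of the linear ones (dominant branches)
        gt = eg.make_ground_truth_laguerre(M=64, H=3, epoch_seconds=8.0, seed=8)
        for s in eg.STATES:
            gt.anf_coeffs[s][:, :, 1] = 0.0
        from dataclasses import replace
        gt2 = replace(gt, noise_sd=eg.calibrate_noise_sd(gt, 20.0))
        ep = eg.simulate_epoch(gt2, "interictal", seed=30)
        u1 = pdm_outputs(gt2.pdms[0], ep.input1)
        u2 = pdm_outputs(gt2.pdms[1], ep.input2)
        model = fit_anfs(u1, u2, [], ep.output, order=3)
        a1 = abs(model.anf_coeffs[0, 0, 0])
        a2 = abs(model.anf_coeffs[0, 0, 1])
        assert a2 < 0.05 * a1


class TestPredict:
    def test_agreement_with_fitted_values(self, ortho_pdms, branch_outputs):
        u1, u2 = branch_outputs
        rng = np.random.default_rng(3)
        O = u1[:, 0] - 0.4 * u2[:, 2] ** 3 + 0.05 * rng.standard_normal(u1.shape[0])
        model = fit_anfs(u1, u2, [(2, 2)], O, order=3)
        # two evaluation paths: regressor matrix x coefficients vs the
        # per-branch polynomial forward sum
        from eegpdm.anf import _anf_regressors
        X = _anf_regressors(u1, u2, [(2, 2)], 3)
        coef = np.concatenate(
            [[model.intercept]]
            + [model.anf_coeffs[i, :, p] for i in (0, 1) for p in range(3)]
            + [[c for _, _, c in model.cross_terms]]
        )
        np.testing.assert_allclose(X @ coef, _predict_from_u(model, u1, u2), atol=1e-8)

    def test_forward_path_matches_simulated_system(self, inspan_gt):
        from dataclasses import replace
        quiet = replace(inspan_gt, noise_sd=0.0)
        ep = eg.simulate_epoch(quiet, "interictal", seed=12)
        u1 = pdm_outputs(quiet.pdms[0], ep.input1)
        u2 = pdm_outputs(quiet.pdms[1], ep.input2)
        model = fit_anfs(u1, u2, [], ep.output, order=3)
        pred = predict_pdm_model(model, quiet.pdms[0], quiet.pdms[1],
                                 ep.input1, ep.input2)
        assert eg.nmse(ep.output, pred) < 1e-6

    def test_zero_coefficients_give_intercept(self, ortho_pdms):
        from eegpdm.anf import SubjectANFModel
        model = SubjectANFModel(
            anf_coeffs=np.zeros((2, 3, 3)), intercept=1.25, order=3
        )
        pred = predict_pdm_model(model, ortho_pdms[0], ortho_pdms[1],
                                 np.ones(100), np.ones(100))
        np.testing.assert_allclose(pred, 1.25, atol=1e-14)


def _predict_from_u(model, u1, u2):
    y = np.full(u1.shape[0], model.intercept)
    for idx, u in ((1, u1), (2, u2)):
        for h in range(u.shape[1]):
            y = y + model.anf(idx, h + 1, u[:, h])
    for i, j, c in model.cross_terms:
        y = y + c * u1[:, i - 1] * u2[:, j - 1]
    return y


class TestModelSelection:
    def test_single_tuple_grid_is_selected(self, shifted_cohort):
        res = model_selection(
            shifted_cohort[:4], alpha_grid=(0.7,), L_grid=(6,),
            H_grid=(5,), order_grid=(3,), M=64,
        )
        assert res.best["tuple"] == (0.7, 6, 5, 3)

    def test_infeasible_H_skipped(self, shifted_cohort):
        res = model_selection(
            shifted_cohort[:4], alpha_grid=(0.7,), L_grid=(6,),
            H_grid=(5, 7), order_grid=(3,), M=64,
        )
        skipped = [g for g in res.grid if "skipped" in g]
        assert len(skipped) == 1 and skipped[0]["tuple"][2] == 7

    def test_empty_grid_rejected(self, shifted_cohort):
        with pytest.raises(ValueError):
            model_selection(shifted_cohort[:2], H_grid=())

    def test_generating_structure_preferred(self, shifted_cohort):
        res = model_selection(
            shifted_cohort[:6], alpha_grid=(0.7,), L_grid=(6,),
            H_grid=(2, 5), order_grid=(1, 3), M=64,
        )
        assert res.best["tuple"] == (0.7, 6, 5, 3)

    def test_serialization_round_trip(self):
        from eegpdm.anf import SubjectANFModel
        m = SubjectANFModel(
            anf_coeffs=np.arange(18, dtype=float).reshape(2, 3, 3),
            cross_terms=[(1, 2, 0.5)],
            intercept=0.3,
            nmse=0.12,
            u_stats=np.ones((2, 3, 4)),
        )
        back = SubjectANFModel.from_json(m.to_json())
        np.testing.assert_array_equal(back.anf_coeffs, m.anf_coeffs)
        assert back.cross_terms == [(1, 2, 0.5)]
        assert back.nmse == pytest.approx(0.12)
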