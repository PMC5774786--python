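"""Gain-coefficient biomarkers and ictal/interictal classification.

The linear gain coefficient of a PDM branch is the slope of the best
straight line fitted (least squares) to its cubic ANF over the branch's
observed operating range; a two-feature Fisher linear discriminant on a
selected pair of gains separates the two states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .anf import SubjectANFModel

__all__ = [
    "linear_gain",
    "gain_table",
    "shapiro_wilk",
    "state_contrast_test",
    "ClassifierResult",
    "train_linear_discriminator",
    "classify",
    "confusion_metrics",
    "feature_pair_search",
]


def linear_gain(anf_coeffs: np.ndarray, u_samples: np.ndarray) -> float:
    """Least-squares slope of the cubic ANF against its observed inputs.

    ``anf_coeffs`` is (a1, a2, a3, ...); the polynomial is evaluated at the
    subject's observed PDM-output samples and regressed on them, so the gain
    reflects the branch's actual operating range.  Requires at least 10
    samples with nonzero variance.
    """
    u = np.asarray(u_samples, dtype=float)
    if u.size < 10:
        raise ValueError("need at least 10 observed PDM-output samples")
    if u.std() == 0.0:
        raise ValueError("zero-variance PDM output: gain undefined")
    c = np.asarray(anf_coeffs, dtype=float)
    f = sum(c[p] * u ** (p + 1) for p in range(c.size))
    du = u - u.mean()
    return float(du @ (f - f.mean()) / (du @ du))


def gain_table(
    anf_models: list[SubjectANFModel],
    u_pairs: list[tuple[np.ndarray, np.ndarray]],
    subject_ids: list[str],
    states: list[str],
) -> pd.DataFrame:
    """Per (subject, state, input, branch) linear gains as a tidy DataFrame.

    ``u_pairs`` supplies each epoch's observed PDM-output matrices
    ``(u1, u2)``; every gain is the slope of the fitted ANF regressed on the
    subject's own observed samples for that branch.
    """
    rows = []
    for model, (u1, u2), sid, state in zip(anf_models, u_pairs, subject_ids, states):
        for input_index, u in ((1, u1), (2, u2)):
            for branch in range(1, model.H + 1):
                gain = linear_gain(
                    model.anf_coeffs[input_index - 1, branch - 1],
                    u[:, branch - 1],
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "state": state,
                        "input": f"input{input_index}",
                        "branch": branch,
                        "gain": gain,
                    }
                )
    return pd.DataFrame(rows)


def shapiro_wilk(values: np.ndarray) -> float:
    """Shapiro–Wilk normality p-value (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if values.std() == 0.0:
        raise ValueError("constant input: normality test degenerate")
    return float(stats.shapiro(values).pvalue)


def state_contrast_test(
    gains_ictal: np.ndarray,
    gains_interictal: np.ndarray,
    mode: str = "paired",
) -> float:
    """Ictal-vs-interictal contrast on one gain feature.

    ``paired`` runs a one-sample t-test on within-subject differences
    (vectors must be subject-aligned); ``welch`` runs the unequal-variance
    two-sample t-test.  Identical paired vectors are degenerate and report
    p = 1.
    """
    a = np.asarray(gains_ictal, dtype=float)
    b = np.asarray(gains_interictal, dtype=float)
    if mode == "paired":
        if a.size != b.size:
            raise ValueError("paired mode requires equal, subject-aligned lengths")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        if np.all(d == 0.0):
            return 1.0
        return float(stats.ttest_rel(a, b).pvalue)
    if mode == "welch":
        if min(a.size, b.size) < 2:
            raise ValueError("need at least 2 samples per group")
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError("mode must be 'paired' or 'welch'")


@dataclass
class ClassifierResult:
    """Fisher linear discriminant on a 2-D gain feature space.

    ``weights @ x > threshold`` classifies an epoch as ictal.  Confusion
    counts refer to the set the classifier was evaluated on; ictal is the
    positive class.
    """

    feature_pair: tuple
    weights: np.ndarray = field(repr=False)
    threshold: float = 0.0
    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    @property
    def sensitivity(self) -> float:
        return confusion_metrics(self.TP, self.FN, self.TN, self.FP)[0]

    @property
    def specificity(self) -> float:
        return confusion_metrics(self.TP, self.FN, self.TN, self.FP)[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "eegpdm.classifier.v1",
                "feature_pair": [list(f) for f in self.feature_pair],
                "weights": self.weights.tolist(),
                "threshold": self.threshold,
                "confusion": {k: getattr(self, k) for k in ("TP", "FN", "TN", "FP")},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierResult":
        d = json.loads(text)
        c = d["confusion"]
        return cls(
            feature_pair=tuple(tuple(f) for f in d["feature_pair"]),
            weights=np.asarray(d["weights"], dtype=float),
            threshold=float(d["threshold"]),
            TP=c["TP"], FN=c["FN"], TN=c["TN"], FP=c["FP"],
        )


def train_linear_discriminator(
    features: np.ndarray,
    labels: np.ndarray,
    feature_pair: tuple = (("input2", 2), ("input2", 4)),
) -> ClassifierResult:
    """Two-class Fisher discriminant with midpoint threshold.

    ``features`` is (n, 2); ``labels`` is boolean/0-1 with 1 = ictal.  The
    projection direction is ``S_w^{-1} (mu_ictal - mu_inter)`` with the
    pooled within-class scatter ``S_w``; the threshold sits at the midpoint
    of the projected class means.  A singular pooled scatter is ridged.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("features must be (n, 2)")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples in each class")
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    Sw = np.cov(X[y], rowvar=False) * (y.sum() - 1) + np.cov(
        X[~y], rowvar=False
    ) * ((~y).sum() - 1)
    if np.linalg.cond(Sw) > 1e12:
        lam = 1e-8 * (np.trace(Sw) / 2 if np.trace(Sw) > 0 else 1.0)
        Sw = Sw + lam * np.eye(2)
    w = np.linalg.solve(Sw, mu1 - mu0)
    thr = float(w @ (mu1 + mu0) / 2.0)
    pred = X @ w > thr
    res = ClassifierResult(
        feature_pair=feature_pair,
        weights=w,
        threshold=thr,
        TP=int(np.sum(pred & y)),
        FN=int(np.sum(~pred & y)),
        TN=int(np.sum(~pred & ~y)),
        FP=int(np.sum(pred & ~y)),
    )
    return res


def classify(result: ClassifierResult, features: np.ndarray) -> np.ndarray:
    """Apply a frozen discriminant; returns a boolean ictal mask."""
    return np.asarray(features, dtype=float) @ result.weights > result.threshold


def confusion_metrics(TP: int, FN: int, TN: int, FP: int) -> tuple[float, float]:
    """Sensitivity and specificity (percent, reported to 0.1)."""
    for v in (TP, FN, TN, FP):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError("confusion counts must be nonnegative integers")
    if TP + FN == 0 or TN + FP == 0:
        raise ValueError("confusion metrics undefined for empty classes")
    sens = round(100.0 * TP / (TP + FN), 1)
    spec = round(100.0 * TN / (TN + FP), 1)
    return sens, spec


def feature_pair_search(
    gains: pd.DataFrame,
) -> list[tuple[tuple, tuple, int]]:
    """Exhaustive two-feature search over (input, branch) gain pairs.

    Trains the Fisher discriminant on every pair of gain features and
    returns ``(feature_a, feature_b, training_errors)`` sorted by error
    count — the systematic version of trying all two-some combinations.
    """
    feats = sorted(
        {(r.input, int(r.branch)) for r in gains.itertuples()},
        key=lambda t: (t[0], t[1]),
    )
    wide = gains.pivot_table(
        index=["subject_id", "state"], columns=["input", "branch"], values="gain"
    )
    labels = np.array([s == "ictal" for _, s in wide.index])
    out = []
    for fa, fb in combinations(feats, 2):
        X = wide[[fa, fb]].to_numpy()
        res = train_linear_discriminator(X, labels, feature_pair=(fa, fb))
        out.append((fa, fb, res.FN + res.FP))
    out.sort(key=lambda t: t[2])
    return out
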