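"""Associated nonlinear functions: PDM outputs, cross-term screening,
per-subject polynomial fits and the (alpha, L, H, order) selection grid.

Each global PDM's convolution output ``u_i(n)`` feeds a static polynomial
(the ANF, cubic by default); products of one PDM output per input model
inter-input modulation and enter the fit only when their correlation with
the output survives a surrogate-calibrated significance screen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.signal import lfilter

from .laguerre_volterra import fit_volterra, laguerre_basis, nmse
from .pdm import GlobalPDMBasis, assemble_Q, extract_global_pdms

__all__ = [
    "SubjectANFModel",
    "ModelSelectionResult",
    "pdm_outputs",
    "select_cross_terms",
    "fit_anfs",
    "predict_pdm_model",
    "model_selection",
]


def pdm_outputs(G: GlobalPDMBasis | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Convolve the input with each global PDM (zero-padded history).

    Returns the (N, H) matrix of branch outputs ``u_i(n)``.
    """
    Gm = G.G if isinstance(G, GlobalPDMBasis) else np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < Gm.shape[0]:
        raise ValueError("input shorter than PDM memory")
    return np.column_stack(
        [lfilter(Gm[:, h], [1.0], x) for h in range(Gm.shape[1])]
    )


def select_cross_terms(
    u1: np.ndarray,
    u2: np.ndarray,
    O: np.ndarray,
    level: float = 0.99,
    n_surrogates: int = 200,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Significance screen for inter-input product terms.

    For every candidate product ``u1_i * u2_j`` the Pearson correlation
    with the output is compared against the ``level`` quantile of its
    absolute correlation under a circular-shift surrogate null (random
    rotations of the product series, which preserve its autocorrelation).
    Returns the 1-based (i, j) pairs exceeding their threshold.  Candidates
    with zero variance are excluded.
    """
    if not 0.9 < level < 1.0:
        raise ValueError("level must be in (0.9, 1)")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    O = np.asarray(O, dtype=float)
    if not (u1.shape[0] == u2.shape[0] == O.size):
        raise ValueError("u1, u2 and O must share the sample dimension")
    n = O.size
    rng = np.random.default_rng(seed)
    Oc = O - O.mean()
    On = np.linalg.norm(Oc)
    selected = []
    for i in range(u1.shape[1]):
        for j in range(u2.shape[1]):
            p = u1[:, i] * u2[:, j]
            pc = p - p.mean()
            pn = np.linalg.norm(pc)
            if pn == 0.0 or On == 0.0:
                continue
            r_obs = abs(pc @ Oc / (pn * On))
            shifts = rng.integers(1, n, size=n_surrogates)
            surr = np.empty(n_surrogates)
            for k, s in enumerate(shifts):
                surr[k] = abs(np.roll(pc, s) @ Oc) / (pn * On)
            if r_obs > np.quantile(surr, level):
                selected.append((i + 1, j + 1))
    return selected


@dataclass
class SubjectANFModel:
    """Per-subject-epoch ANF fit on a fixed global PDM basis.

    ``anf_coeffs[input, branch]`` holds (a1, .., a_order); ``cross_terms``
    holds 1-based (branch_i, branch_j, coefficient) triples; ``u_stats``
    records per-input-branch observed PDM-output moments (mean, sd, min,
    max) defining each ANF's operating range.
    """

    anf_coeffs: np.ndarray = field(repr=False)  # (2, H, order)
    cross_terms: list = field(default_factory=list)
    intercept: float = 0.0
    nmse: float = np.nan
    u_stats: np.ndarray | None = field(default=None, repr=False)  # (2, H, 4)
    order: int = 3

    @property
    def H(self) -> int:
        return self.anf_coeffs.shape[1]

    def anf(self, input_index: int, branch: int, u: np.ndarray) -> np.ndarray:
        """Evaluate the fitted polynomial of one branch (1-based indices)."""
        c = self.anf_coeffs[input_index - 1, branch - 1]
        u = np.asarray(u, dtype=float)
        return sum(c[p] * u ** (p + 1) for p in range(self.order))

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "eegpdm.anf.v1",
                "order": self.order,
                "anf_coeffs": self.anf_coeffs.tolist(),
                "cross_terms": [list(t) for t in self.cross_terms],
                "intercept": self.intercept,
                "nmse": None if np.isnan(self.nmse) else self.nmse,
                "u_stats": None if self.u_stats is None else self.u_stats.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SubjectANFModel":
        d = json.loads(text)
        return cls(
            anf_coeffs=np.asarray(d["anf_coeffs"], dtype=float),
            cross_terms=[(int(a), int(b), float(c)) for a, b, c in d["cross_terms"]],
            intercept=float(d["intercept"]),
            nmse=np.nan if d.get("nmse") is None else float(d["nmse"]),
            u_stats=None if d.get("u_stats") is None else np.asarray(d["u_stats"]),
            order=int(d["order"]),
        )


def _anf_regressors(
    u1: np.ndarray, u2: np.ndarray, cross_pairs: list[tuple[int, int]], order: int
) -> np.ndarray:
    """Regressor matrix: intercept | powers 1..order of every branch | products."""
    cols = [np.ones((u1.shape[0], 1))]
    for u in (u1, u2):
        for p in range(1, order + 1):
            cols.append(u**p)
    for i, j in cross_pairs:
        cols.append((u1[:, i - 1] * u2[:, j - 1])[:, None])
    return np.concatenate(cols, axis=1)


def fit_anfs(
    u1: np.ndarray,
    u2: np.ndarray,
    cross_pairs: list[tuple[int, int]],
    O: np.ndarray,
    order: int = 3,
    *,
    ridge_threshold: float = 1e10,
) -> SubjectANFModel:
    """Joint least-squares fit of all ANFs, cross terms and the intercept.

    One regression of the output on {u_i^p, p = 1..order} for every branch
    of both inputs plus the selected cross products; coefficients are
    partitioned into per-branch polynomials.  An ill-conditioned regressor
    matrix triggers a small ridge penalty (logged via warning).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    O = np.asarray(O, dtype=float)
    H1, H2 = u1.shape[1], u2.shape[1]
    n_par = 1 + order * (H1 + H2) + len(cross_pairs)
    if O.size < 10 * n_par:
        raise ValueError(
            f"need at least 10 samples per parameter: {O.size} < {10 * n_par}"
        )
    X = _anf_regressors(u1, u2, cross_pairs, order)
    cond = np.linalg.cond(X)
    if cond > ridge_threshold:
        lam = 1e-8 * np.trace(X.T @ X) / X.shape[1]
        warnings.warn(
            f"regressor condition number {cond:.2e}; applying ridge {lam:.2e}",
            stacklevel=2,
        )
        coef = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ O)
    else:
        coef, *_ = np.linalg.lstsq(X, O, rcond=None)
    intercept = float(coef[0])
    anf = np.zeros((2, max(H1, H2), order))
    k = 1
    for idx, H in ((0, H1), (1, H2)):
        for p in range(order):
            anf[idx, :H, p] = coef[k : k + H]
            k += H
    cross_terms = [
        (i, j, float(c)) for (i, j), c in zip(cross_pairs, coef[k:])
    ]
    u_stats = np.zeros((2, max(H1, H2), 4))
    for idx, u in ((0, u1), (1, u2)):
        u_stats[idx, : u.shape[1]] = np.column_stack(
            [u.mean(0), u.std(0), u.min(0), u.max(0)]
        )
    model = SubjectANFModel(
        anf_coeffs=anf,
        cross_terms=cross_terms,
        intercept=intercept,
        u_stats=u_stats,
        order=order,
    )
    model.nmse = nmse(O, X @ coef)
    return model


def predict_pdm_model(
    model: SubjectANFModel,
    G1: GlobalPDMBasis | np.ndarray,
    G2: GlobalPDMBasis | np.ndarray,
    T: np.ndarray,
    F: np.ndarray,
) -> np.ndarray:
    """Forward-evaluate the fitted PDM model on an input pair."""
    u1 = pdm_outputs(G1, T)
    u2 = pdm_outputs(G2, F)
    y = np.full(u1.shape[0], model.intercept)
    for idx, u in ((1, u1), (2, u2)):
        for h in range(u.shape[1]):
            y = y + model.anf(idx, h + 1, u[:, h])
    for i, j, c in model.cross_terms:
        y = y + c * u1[:, i - 1] * u2[:, j - 1]
    return y


@dataclass
class ModelSelectionResult:
    """Grid-search record: one row per (alpha, L, H, order) tuple."""

    grid: list = field(default_factory=list)  # dicts with tuple, nmse, bic
    best: dict | None = None


def _fit_epoch_stack(epochs, alpha, L, M, H, order):
    """Kernel estimation → PDM extraction → per-epoch ANF fits; returns
    per-epoch (RSS, N, n_params, nmse)."""
    basis = laguerre_basis(alpha, L, M)
    models, sds1, sds2, states = [], [], [], []
    for ep in epochs:
        models.append(fit_volterra(ep.input1, ep.input2, ep.output, basis))
        sds1.append(float(ep.input1.std()))
        sds2.append(float(ep.input2.std()))
        states.append(ep.state)
    G1 = extract_global_pdms(
        assemble_Q(models, "input1", sds1, states), H, input_label="input1",
        fs=epochs[0].fs,
    )
    G2 = extract_global_pdms(
        assemble_Q(models, "input2", sds2, states), H, input_label="input2",
        fs=epochs[0].fs,
    )
    records = []
    for ep in epochs:
        u1 = pdm_outputs(G1, ep.input1)
        u2 = pdm_outputs(G2, ep.input2)
        anf = fit_anfs(u1, u2, [], ep.output, order)
        n = ep.output.size
        rss = anf.nmse * np.sum((ep.output - ep.output.mean()) ** 2)
        records.append((rss, n, 1 + order * 2 * G1.H, anf.nmse))
    return records, (G1, G2)


def model_selection(
    epochs: list,
    alpha_grid=(0.7,),
    L_grid=(6,),
    H_grid=(2, 5),
    order_grid=(1, 3),
    M: int = 64,
) -> ModelSelectionResult:
    """Global search over (alpha, L, H, order) minimising mean BIC.

    For every tuple the full pipeline (kernel estimation, PDM extraction,
    ANF fit) runs on each training epoch; the score is
    ``BIC = N ln(RSS/N) + p ln(N)`` with p the ANF-stage parameter count,
    averaged over epochs.  Ties break toward fewer parameters.  Infeasible
    tuples (H above the achievable rank, or too many parameters for the
    epoch length) are skipped with a note.
    """
    if not (len(alpha_grid) and len(L_grid) and len(H_grid) and len(order_grid)):
        raise ValueError("all grids must be nonempty")
    result = ModelSelectionResult()
    for alpha, L, H, order in product(alpha_grid, L_grid, H_grid, order_grid):
        if H > min(L, M):
            result.grid.append(
                {"tuple": (alpha, L, H, order), "skipped": "H exceeds basis rank"}
            )
            continue
        try:
            records, _ = _fit_epoch_stack(epochs, alpha, L, M, H, order)
        except ValueError as exc:
            result.grid.append(
                {"tuple": (alpha, L, H, order), "skipped": str(exc)}
            )
            continue
        bics = [n * np.log(rss / n) + p * np.log(n) for rss, n, p, _ in records]
        entry = {
            "tuple": (alpha, L, H, order),
            "n_params": records[0][2],
            "mean_nmse": float(np.mean([r[3] for r in records])),
            "bic": float(np.mean(bics)),
        }
        result.grid.append(entry)
        if (
            result.best is None
            or entry["bic"] < result.best["bic"] - 1e-12
            or (
                abs(entry["bic"] - result.best["bic"]) <= 1e-12
                and entry["n_params"] < result.best["n_params"]
            )
        ):
            result.best = entry
    if result.best is None:
        raise ValueError("no feasible tuple in the selection grid")
    return result
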