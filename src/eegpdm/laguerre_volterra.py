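"""Two-input second-order Volterra modelling via the discrete Laguerre expansion.

The model predicts one output channel ``O(n)`` from two input channels
``T(n)`` and ``F(n)`` through a zeroth-order constant, first-order kernels
``kT``/``kF`` (linear impulse responses over ``M`` lags), second-order self
kernels ``kTT``/``kFF`` (pairwise lag interactions within one input) and one
cross kernel ``kTF`` (lag interactions between the inputs).  Kernels are
expanded on the orthonormal discrete Laguerre basis, which compresses the
estimation into a small coefficient vector fit by linear least squares.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "LaguerreBasis",
    "VolterraModel",
    "laguerre_basis",
    "filter_inputs",
    "build_design_matrix",
    "estimate_beta",
    "reconstruct_kernels",
    "predict_volterra",
    "fit_volterra",
    "nmse",
]


def _laguerre_closed_form(alpha: float, L: int, M: int) -> np.ndarray:
    """Evaluate the closed-form discrete Laguerre functions.

    ``b_j(m) = alpha^((m-j)/2) (1-alpha)^(1/2)
               * sum_k (-1)^k C(m,k) C(j,k) alpha^(j-k) (1-alpha)^k``

    with function index ``j = 0..L-1`` and lag ``m = 0..M-1``.
    """
    B = np.zeros((M, L))
    for j in range(L):
        for m in range(M):
            s = 0.0
            for k in range(j + 1):
                s += (
                    (-1.0) ** k
                    * math.comb(m, k)
                    * math.comb(j, k)
                    * alpha ** (j - k)
                    * (1.0 - alpha) ** k
                )
            B[m, j] = alpha ** ((m - j) / 2.0) * math.sqrt(1.0 - alpha) * s
    return B


def _laguerre_recurrence(alpha: float, L: int, M: int) -> np.ndarray:
    """Discrete Laguerre functions by the standard two-term recurrence.

    ``b_0(m) = alpha^(m/2) sqrt(1-alpha)`` and, for ``j >= 1``,
    ``b_j(m) = sqrt(alpha) b_j(m-1) + sqrt(alpha) b_{j-1}(m) - b_{j-1}(m-1)``
    (terms with negative lag are zero).  Used as an internal cross-check of
    the closed form.
    """
    B = np.zeros((M, L))
    ra = math.sqrt(alpha)
    B[:, 0] = math.sqrt(1.0 - alpha) * alpha ** (np.arange(M) / 2.0)
    for j in range(1, L):
        B[0, j] = ra * B[0, j - 1]
        for m in range(1, M):
            B[m, j] = ra * B[m - 1, j] + ra * B[m, j - 1] - B[m - 1, j - 1]
    return B


@dataclass(frozen=True)
class LaguerreBasis:
    """Orthonormal discrete Laguerre basis over ``M`` lags.

    Attributes
    ----------
    alpha : float
        Decay parameter in (0, 1); larger alpha means slower decay and
        longer effective memory.
    L : int
        Number of basis functions.
    M : int
        Number of lags (samples of system memory).
    B : ndarray, shape (M, L)
        Basis matrix; column ``j`` is ``b_j(m)`` for ``m = 0..M-1``.
    """

    alpha: float
    L: int
    M: int
    B: np.ndarray = field(repr=False)


def laguerre_basis(alpha: float = 0.7, L: int = 6, M: int = 64) -> LaguerreBasis:
    """Construct the discrete Laguerre basis.

    Parameters follow the configuration selected for EEG epochs (six
    functions, decay 0.7); ``M = 64`` samples is 250 ms at 256 Hz, past the
    point where all basis functions have decayed to ~1% of their peak.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if M < L:
        raise ValueError(f"M must be >= L, got M={M}, L={L}")
    B = _laguerre_closed_form(alpha, L, M)
    return LaguerreBasis(alpha=alpha, L=L, M=M, B=B)


def filter_inputs(basis: LaguerreBasis, x: np.ndarray) -> np.ndarray:
    """Convolve a signal with each Laguerre function ("key variables").

    Returns the matrix ``v`` with ``v[n, j] = sum_m b_j(m) x(n - m)``,
    a causal FIR convolution truncated to ``M`` lags with zero-padded
    pre-history.  The first sample (n = 0) is dropped so the row count is
    ``N = T - 1`` for an input of length ``T``, matching the regression
    convention used throughout this module.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if x.size < basis.M:
        raise ValueError(f"input length {x.size} < memory M={basis.M}")
    v = np.empty((x.size, basis.L))
    for j in range(basis.L):
        v[:, j] = lfilter(basis.B[:, j], [1.0], x)
    return v[1:]


def _pair_index(L: int) -> list[tuple[int, int]]:
    """Unique second-order index pairs (j1, j2<=j1), row-major, 0-based."""
    return [(j1, j2) for j1 in range(L) for j2 in range(j1 + 1)]


def build_design_matrix(vT: np.ndarray, vF: np.ndarray) -> np.ndarray:
    """Assemble the least-squares design matrix ``V``.

    Column order is fixed: ``[1 | V_F | V_T | V_FF | V_TT | V_TF]``.  Each
    second-order block holds the L(L+1)/2 unique elementwise products
    ``v_{j1} * v_{j2}`` for j1 = 0..L-1, j2 = 0..j1; the TF block pairs the
    F key variable at j1 with the T key variable at j2.  Total column count
    is ``1 + 2L + 3 L(L+1)/2``.
    """
    vT = np.asarray(vT, dtype=float)
    vF = np.asarray(vF, dtype=float)
    if vT.shape != vF.shape:
        raise ValueError(f"key-variable shapes differ: {vT.shape} vs {vF.shape}")
    N, L = vT.shape
    pairs = _pair_index(L)
    cols = [np.ones((N, 1)), vF, vT]
    for u, w in ((vF, vF), (vT, vT), (vF, vT)):
        block = np.empty((N, len(pairs)))
        for c, (j1, j2) in enumerate(pairs):
            block[:, c] = u[:, j1] * w[:, j2]
        cols.append(block)
    return np.concatenate(cols, axis=1)


def estimate_beta(
    V: np.ndarray, O: np.ndarray, *, normal_equations: bool = False
) -> tuple[np.ndarray, float]:
    """Least-squares expansion coefficients ``beta`` minimising ||O - V beta||².

    Solved through an orthogonal decomposition (LAPACK gelsd) rather than by
    forming ``VᵀV``, for conditioning; ``normal_equations=True`` switches to
    the literal ``(VᵀV)⁻¹VᵀO`` path for comparison.  Returns ``(beta,
    residual_variance)``.  A rank-deficient design produces the minimum-norm
    solution with a warning.
    """
    V = np.asarray(V, dtype=float)
    O = np.asarray(O, dtype=float).ravel()
    if V.shape[0] != O.size:
        raise ValueError("row count of V must match length of O")
    if V.shape[0] <= V.shape[1]:
        raise ValueError(
            f"need more rows than columns: V is {V.shape[0]}x{V.shape[1]}"
        )
    if normal_equations:
        G = V.T @ V
        beta = np.linalg.solve(G, V.T @ O)
    else:
        beta, _, rank, _ = np.linalg.lstsq(V, O, rcond=None)
        if rank < V.shape[1]:
            warnings.warn(
                f"design matrix rank {rank} < {V.shape[1]} columns; "
                "returning minimum-norm solution",
                stacklevel=2,
            )
    resid = O - V @ beta
    return beta, float(resid @ resid / resid.size)


def _partition_beta(beta: np.ndarray, L: int) -> dict[str, np.ndarray]:
    """Split the flat coefficient vector by design-matrix block."""
    P = L * (L + 1) // 2
    expected = 1 + 2 * L + 3 * P
    if beta.size != expected:
        raise ValueError(f"beta length {beta.size} != {expected} for L={L}")
    out = {}
    i = 0
    for name, size in (
        ("beta0", 1),
        ("beta_F", L),
        ("beta_T", L),
        ("beta_FF", P),
        ("beta_TT", P),
        ("beta_TF", P),
    ):
        out[name] = beta[i : i + size].copy()
        i += size
    return out


def _coeff_matrix(tri: np.ndarray, L: int, *, symmetrize: bool) -> np.ndarray:
    """Expand triangular second-order coefficients into an L×L matrix.

    For self kernels the off-diagonal coefficients are split evenly across
    (j1, j2) and (j2, j1) so the reconstructed kernel is symmetric while the
    implied quadratic form is unchanged.  The cross kernel keeps a single
    orientation: C[j2, j1] = beta(j1, j2), i.e. the j2 index runs along the
    T lag axis and j1 along the F lag axis, exactly as the design-matrix
    product (b_{j1}*F)·(b_{j2}*T) dictates.
    """
    C = np.zeros((L, L))
    for c, (j1, j2) in enumerate(_pair_index(L)):
        if symmetrize:
            if j1 == j2:
                C[j1, j2] = tri[c]
            else:
                C[j1, j2] = C[j2, j1] = tri[c] / 2.0
        else:
            C[j2, j1] = tri[c]
    return C


@dataclass
class VolterraModel:
    """Estimated two-input second-order Volterra model for one epoch.

    ``beta`` holds the expansion coefficients partitioned by block; kernels
    are reconstructed on the lag grid.  ``kTT``/``kFF`` are symmetric by
    construction; ``kTF[m1, m2]`` weights ``T(n-m1) F(n-m2)``.
    """

    basis: LaguerreBasis
    beta: dict[str, np.ndarray]
    k0: float
    kT: np.ndarray
    kF: np.ndarray
    kTT: np.ndarray
    kFF: np.ndarray
    kTF: np.ndarray
    nmse: float = np.nan
    residual_variance: float = np.nan

    def to_json(self) -> str:
        payload = {
            "format": "eegpdm.volterra.v1",
            "alpha": self.basis.alpha,
            "L": self.basis.L,
            "M": self.basis.M,
            "column_order": "1|VF|VT|VFF|VTT|VTF;pairs row-major (j1, j2<=j1)",
            "beta": {k: v.tolist() for k, v in self.beta.items()},
            "nmse": None if np.isnan(self.nmse) else self.nmse,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "VolterraModel":
        d = json.loads(text)
        basis = laguerre_basis(d["alpha"], d["L"], d["M"])
        beta = np.concatenate(
            [np.asarray(d["beta"][k], dtype=float)
             for k in ("beta0", "beta_F", "beta_T", "beta_FF", "beta_TT", "beta_TF")]
        )
        model = reconstruct_kernels(beta, basis)
        model.nmse = np.nan if d.get("nmse") is None else float(d["nmse"])
        return model


def reconstruct_kernels(beta: np.ndarray | dict, basis: LaguerreBasis) -> VolterraModel:
    """Rebuild lag-domain kernels from expansion coefficients.

    First-order kernels are ``B @ beta_1``; second-order kernels are
    ``B C Bᵀ`` where ``C`` is the (symmetrized, for self kernels)
    coefficient matrix.
    """
    if isinstance(beta, dict):
        parts = beta
    else:
        parts = _partition_beta(np.asarray(beta, dtype=float), basis.L)
    B = basis.B
    kT = B @ parts["beta_T"]
    kF = B @ parts["beta_F"]
    kTT = B @ _coeff_matrix(parts["beta_TT"], basis.L, symmetrize=True) @ B.T
    kFF = B @ _coeff_matrix(parts["beta_FF"], basis.L, symmetrize=True) @ B.T
    # enforce exact symmetry (matmul rounding is not order-invariant)
    kTT = (kTT + kTT.T) / 2.0
    kFF = (kFF + kFF.T) / 2.0
    kTF = B @ _coeff_matrix(parts["beta_TF"], basis.L, symmetrize=False) @ B.T
    return VolterraModel(
        basis=basis,
        beta=parts,
        k0=float(parts["beta0"][0]),
        kT=kT,
        kF=kF,
        kTT=kTT,
        kFF=kFF,
        kTF=kTF,
    )


def lag_matrix(x: np.ndarray, M: int) -> np.ndarray:
    """Zero-padded lag embedding: ``X[n, m] = x(n - m)`` for m = 0..M-1."""
    x = np.asarray(x, dtype=float)
    X = np.zeros((x.size, M))
    for m in range(M):
        X[m:, m] = x[: x.size - m]
    return X


def nmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Normalized mean-square error: RSS over total sum of squares about the mean."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    resid = observed - predicted
    denom = float(np.sum((observed - observed.mean()) ** 2))
    if denom == 0.0:
        return float("nan")
    return float(resid @ resid / denom)


def predict_volterra(
    model: VolterraModel,
    T: np.ndarray,
    F: np.ndarray,
    O: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Evaluate the Volterra forward sum on an epoch.

    Returns the full-length noise-free prediction (zero-padded history) and,
    when a reference output is supplied, its NMSE computed over samples
    n >= 1 (the regression rows).
    """
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    M = model.basis.M
    if T.size < M or F.size < M:
        raise ValueError("inputs shorter than model memory")
    XT = lag_matrix(T, M)
    XF = lag_matrix(F, M)
    pred = (
        model.k0
        + XT @ model.kT
        + XF @ model.kF
        + ((XT @ model.kTT) * XT).sum(axis=1)
        + ((XF @ model.kFF) * XF).sum(axis=1)
        + ((XT @ model.kTF) * XF).sum(axis=1)
    )
    err = nmse(np.asarray(O, dtype=float)[1:], pred[1:]) if O is not None else np.nan
    return pred, err


def fit_volterra(
    T: np.ndarray,
    F: np.ndarray,
    O: np.ndarray,
    basis: LaguerreBasis | None = None,
    *,
    normal_equations: bool = False,
) -> VolterraModel:
    """Estimate the full model for one epoch: key variables → design matrix →
    least squares → kernel reconstruction.  Training NMSE is stored on the
    returned model."""
    if basis is None:
        basis = laguerre_basis()
    vT = filter_inputs(basis, np.asarray(T, dtype=float))
    vF = filter_inputs(basis, np.asarray(F, dtype=float))
    V = build_design_matrix(vT, vF)
    O = np.asarray(O, dtype=float)
    beta, resid_var = estimate_beta(V, O[1:], normal_equations=normal_equations)
    model = reconstruct_kernels(beta, basis)
    model.residual_variance = resid_var
    model.nmse = nmse(O[1:], V @ np.concatenate([v for v in model.beta.values()]))
    return model
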