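"""Global principal dynamic modes: cross-subject kernel SVD and spectra.

The first- and second-order self kernels of every subject-state epoch are
stacked (interictal block first, then ictal) into one matrix per input; the
leading singular vectors along the lag dimension are the global PDMs shared
by the whole cohort.  Second-order kernels are scaled by the epoch's input
standard deviation so first- and second-order contributions are commensurate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .laguerre_volterra import VolterraModel

__all__ = [
    "GlobalPDMBasis",
    "assemble_Q",
    "extract_global_pdms",
    "pdm_spectrum",
    "dominant_peaks",
]


@dataclass
class GlobalPDMBasis:
    """Global PDM basis for one input.

    ``G`` holds H unit-norm PDM waveforms over M lags (columns ordered by
    decreasing singular value); each column's sign is fixed so its
    largest-magnitude element is positive, making the extraction
    deterministic.
    """

    input_label: str
    G: np.ndarray = field(repr=False)
    singular_values: np.ndarray = field(repr=False)
    fs: float = 256.0

    @property
    def M(self) -> int:
        return self.G.shape[0]

    @property
    def H(self) -> int:
        return self.G.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "eegpdm.pdmbasis.v1",
                "sign_convention": "largest-magnitude element positive",
                "input_label": self.input_label,
                "fs": self.fs,
                "G": self.G.tolist(),
                "singular_values": self.singular_values.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GlobalPDMBasis":
        d = json.loads(text)
        return cls(
            input_label=d["input_label"],
            G=np.asarray(d["G"], dtype=float),
            singular_values=np.asarray(d["singular_values"], dtype=float),
            fs=float(d["fs"]),
        )


def _kernels_for_input(model: VolterraModel, input_label: str):
    if input_label in ("T", "input1", "1"):
        return model.kT, model.kTT
    if input_label in ("F", "input2", "2"):
        return model.kF, model.kFF
    raise ValueError(f"unknown input label {input_label!r}")


def assemble_Q(
    models: list[VolterraModel],
    input_label: str,
    input_sds: list[float],
    states: list[str] | None = None,
) -> np.ndarray:
    """Stack per-epoch kernel blocks into the cross-subject matrix Q.

    Each epoch contributes a (1 + M) x M block: its first-order kernel for
    the named input as one row, then its second-order self kernel scaled by
    the epoch's input standard deviation.  Cross kernels are excluded.  When
    state labels are given, interictal blocks are stacked before ictal ones;
    the SVD is invariant to this row order, it is kept for auditability.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 epoch models")
    if len(input_sds) != len(models):
        raise ValueError("one input sd per model required")
    M = models[0].basis.M
    if any(m.basis.M != M for m in models):
        raise ValueError("all models must share the same memory M")
    order = range(len(models))
    if states is not None:
        if len(states) != len(models):
            raise ValueError("one state label per model required")
        order = sorted(order, key=lambda i: states[i] != "interictal")
    blocks = []
    for i in order:
        k1, k2 = _kernels_for_input(models[i], input_label)
        blocks.append(k1[None, :])
        blocks.append(input_sds[i] * k2)
    return np.vstack(blocks)


def extract_global_pdms(
    Q: np.ndarray, H: int = 5, *, input_label: str = "", fs: float = 256.0
) -> GlobalPDMBasis:
    """SVD of Q; the H leading lag-dimension singular vectors are the PDMs.

    If H exceeds the numerical rank of Q the basis is truncated with a
    warning.  Columns are unit-norm with the sign convention applied.
    """
    Q = np.asarray(Q, dtype=float)
    if H > min(Q.shape):
        raise ValueError(f"H={H} exceeds min(Q.shape)={min(Q.shape)}")
    _, svals, Vt = np.linalg.svd(Q, full_matrices=False)
    tol = svals[0] * max(Q.shape) * np.finfo(float).eps if svals.size else 0.0
    rank = int(np.sum(svals > tol))
    if H > rank:
        warnings.warn(
            f"requested H={H} exceeds numerical rank {rank}; truncating",
            stacklevel=2,
        )
        H = rank
    G = Vt[:H].T.copy()
    for h in range(H):
        col = G[:, h]
        if col[np.argmax(np.abs(col))] < 0:
            G[:, h] = -col
    return GlobalPDMBasis(
        input_label=input_label, G=G, singular_values=svals[:H].copy(), fs=fs
    )


def pdm_spectrum(
    G: np.ndarray | GlobalPDMBasis, fs: float | None = None, nfft: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded FFT magnitude spectrum of each PDM over [0, fs/2].

    Returns ``(freqs, mags)`` with ``mags[:, h]`` the magnitude spectrum of
    PDM h at resolution fs/nfft.
    """
    if isinstance(G, GlobalPDMBasis):
        fs = G.fs if fs is None else fs
        G = G.G
    if fs is None:
        raise ValueError("fs required when G is a bare matrix")
    if nfft < G.shape[0]:
        raise ValueError("nfft must be >= M")
    mags = np.abs(np.fft.rfft(G, n=nfft, axis=0))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, mags


def dominant_peaks(
    freqs: np.ndarray, mag: np.ndarray, min_prominence: float = 0.1
) -> list[float]:
    """Frequencies of local spectral maxima, sorted by decreasing magnitude.

    ``min_prominence`` is relative to the spectrum's maximum.  Endpoint
    maxima (e.g. a low-pass peak at 0 Hz) are included.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.size == 0:
        raise ValueError("empty spectrum")
    top = mag.max()
    if top == 0.0:
        return []
    # pad so maxima at either endpoint register as peaks
    padded = np.concatenate([[-np.inf], mag, [-np.inf]])
    idx, _ = find_peaks(padded, prominence=min_prominence * top)
    idx -= 1
    order = np.argsort(mag[idx])[::-1]
    return [float(freqs[i]) for i in idx[order]]
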