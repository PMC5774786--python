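"""Epoch conditioning: low-pass filtering, demean/detrend, Grubbs outlier repair.

The pipeline order is filter → demean/detrend → Grubbs, applied per channel
per epoch.  Flagged outlier samples are replaced by linear interpolation of
their neighbours rather than deleted, so the uniform sampling grid needed by
the convolution stages is preserved; the flag list is kept for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import butter, detrend as _sp_detrend, filtfilt, lfilter

__all__ = [
    "PreprocessConfig",
    "lowpass_butterworth",
    "demean_detrend",
    "grubbs_clean",
    "preprocess_series",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    cutoff_hz : low-pass cutoff (Hz); filter_order : Butterworth order;
    grubbs_alpha : per-iteration two-sided significance level;
    detrend_kind : 'linear' removes the least-squares line (and hence the
    mean), 'constant' removes only the mean; zero_phase : apply the filter
    forward-backward instead of causally.
    """

    cutoff_hz: float = 40.0
    filter_order: int = 2
    grubbs_alpha: float = 0.05
    detrend_kind: str = "linear"
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0.0 < self.grubbs_alpha < 1.0:
            raise ValueError("grubbs_alpha must be in (0, 1)")
        if self.detrend_kind not in ("linear", "constant"):
            raise ValueError("detrend_kind must be 'linear' or 'constant'")


def lowpass_butterworth(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Digital Butterworth low-pass of the configured order and cutoff.

    Causal (forward-only) by default; ``cfg.zero_phase`` selects
    forward-backward filtering.  The cutoff must be below Nyquist.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if cfg.cutoff_hz >= fs / 2.0:
        raise ValueError(
            f"cutoff {cfg.cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    if x.size <= 3 * cfg.filter_order:
        raise ValueError("series too short for the filter order")
    b, a = butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, x) if cfg.zero_phase else lfilter(b, a, x)


def demean_detrend(x: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Remove the mean and (by default) the least-squares linear trend."""
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return _sp_detrend(x, type=cfg.detrend_kind)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_clean(
    x: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs outlier test with interpolation repair.

    Each iteration flags the single most extreme sample if its statistic
    ``G = max|x - mean| / sd`` exceeds the critical value at
    ``cfg.grubbs_alpha``; the sample is replaced by linear interpolation of
    the nearest unflagged neighbours and the test repeats until no sample
    exceeds the threshold.  A zero-variance series is returned unchanged.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float).copy()
    n = x.size
    if n < 7:
        raise ValueError("need at least 7 samples for a meaningful Grubbs test")
    good = np.ones(n, dtype=bool)
    # flagged samples leave the sample for subsequent iterations (the test
    # statistic is computed on the remaining data), guaranteeing termination
    while good.sum() >= 7:
        xs = x[good]
        s = xs.std(ddof=1)
        if s == 0.0:
            break
        dev = np.abs(xs - xs.mean())
        k = int(np.argmax(dev))
        if dev[k] / s <= grubbs_critical(xs.size, cfg.grubbs_alpha):
            break
        good[np.flatnonzero(good)[k]] = False
    flagged = sorted(int(i) for i in np.flatnonzero(~good))
    if flagged:
        idx = np.flatnonzero(good)
        x[~good] = np.interp(flagged, idx, x[idx])
    return x, flagged


def preprocess_series(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[int]]:
    """Full conditioning chain for one channel: filter → detrend → Grubbs."""
    cfg = cfg or PreprocessConfig()
    y = lowpass_butterworth(x, fs, cfg)
    y = demean_detrend(y, cfg)
    return grubbs_clean(y, cfg)
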