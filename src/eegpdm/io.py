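"""Optional readers for real recordings.

Delimited-text epochs are handled in :mod:`eegpdm.synthetic`
(``read_epoch`` / ``read_cohort``); this module adds an EDF reader for
10-20-montage recordings, pulling a dual-input/output triplet from named
bipolar channels.  The EDF backend (mne) is imported lazily so the core
package has no hard dependency on it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synthetic import EpochTriplet

__all__ = ["read_edf_epoch", "DEFAULT_CHANNEL_MAP"]

#: default bipolar derivations: temporal and frontal inputs, parieto-occipital output
DEFAULT_CHANNEL_MAP = {
    "input1": "T7-P7",
    "input2": "FP1-F3",
    "output": "P3-O1",
}


def read_edf_epoch(
    path: Path,
    channel_map: dict | None = None,
    *,
    start_s: float = 0.0,
    duration_s: float = 69.0,
    subject_id: str | None = None,
    state: str = "interictal",
) -> EpochTriplet:
    """Extract one epoch triplet from an EDF recording.

    ``channel_map`` maps the roles input1/input2/output to channel names as
    stored in the file (case-insensitive match).  Requires the optional
    ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF reading requires the optional 'mne' dependency "
            "(pip install eegpdm[edf])"
        ) from exc
    cmap = {**DEFAULT_CHANNEL_MAP, **(channel_map or {})}
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    lookup = {name.lower(): name for name in raw.ch_names}
    series = {}
    for role in ("input1", "input2", "output"):
        wanted = cmap[role].lower()
        if wanted not in lookup:
            raise KeyError(
                f"channel {cmap[role]!r} not in file; available: {raw.ch_names}"
            )
        series[role] = lookup[wanted]
    fs = float(raw.info["sfreq"])
    start = int(round(start_s * fs))
    stop = start + int(round(duration_s * fs))
    data = raw.get_data(picks=[series[r] for r in ("input1", "input2", "output")],
                        start=start, stop=stop)
    return EpochTriplet(
        input1=np.asarray(data[0], dtype=float),
        input2=np.asarray(data[1], dtype=float),
        output=np.asarray(data[2], dtype=float),
        fs=fs,
        subject_id=subject_id or Path(path).stem,
        state=state,
    )
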