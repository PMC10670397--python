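"""Signal normalization, label handling, epoching and R-peak detection.

The preprocessing contract, applied once per recording before any feature
extraction:

1. ECG and respiratory effort are Z-score normalized *per recording* (mean 0,
   SD 1).  Motion counts are left on their native nonnegative scale.
2. ``Wake`` and ``Caretaking`` annotations are merged into the single wake
   class ``CTW``; ``Unknown`` epochs are excluded from analysis.
3. The retained timeline is cut into non-overlapping half-open 30-s windows
   ``[30i, 30(i+1))`` — one :class:`Epoch` per retained annotation row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import EPOCH_S, STATES
from .io import ANNOTATION_LABELS, Recording

__all__ = [
    "Epoch",
    "zscore_normalize",
    "merge_labels",
    "epochize",
    "detect_rpeaks",
    "preprocess_recording",
]

#: Raw-label -> analysis-label map; ``None`` marks exclusion.
_LABEL_MAP = {
    "AS": "AS",
    "QS": "QS",
    "Wake": "CTW",
    "Caretaking": "CTW",
    "CTW": "CTW",
    "Unknown": "Unknown",
}


@dataclass
class Epoch:
    """One 30-s analysis window of a preprocessed recording."""

    index: int
    label: str
    r_times: np.ndarray | None = None  # absolute seconds, within the window
    ecg: np.ndarray | None = None
    resp: np.ndarray | None = None
    motion: np.ndarray | None = None
    ecg_rate: float = 500.0
    resp_rate: float = 16.0
    motion_rate: float = 8.0

    @property
    def start_s(self) -> float:
        return self.index * EPOCH_S


def zscore_normalize(series: np.ndarray) -> np.ndarray:
    """Normalize a series to mean 0, SD 1 (population SD).

    Raises ``ValueError`` on series shorter than 2 samples or with zero
    variance; normalization is an affine map, so any affine transform of the
    input yields an identical output.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot Z-score a constant series (zero variance)")
    return (x - x.mean()) / sd


def merge_labels(labels) -> pd.Series:
    """Map raw 5-state annotations onto the 3-class analysis vocabulary.

    ``Wake`` and ``Caretaking`` become ``CTW``; ``AS``/``QS`` pass through;
    ``Unknown`` is kept but marks the epoch for exclusion downstream.
    """
    out = []
    for lab in labels:
        if lab not in _LABEL_MAP:
            raise ValueError(
                f"unrecognized label {lab!r}; expected one of {sorted(ANNOTATION_LABELS)}"
            )
        out.append(_LABEL_MAP[lab])
    return pd.Series(out, dtype=object)


def detect_rpeaks(ecg: np.ndarray, rate: float) -> np.ndarray:
    """Detect R-peak times (s) in a single-lead ECG.

    Pan-Tompkins-style detector: 5-40 Hz band-pass, squared derivative,
    120-ms moving-window integration, adaptive threshold at 25 % of the
    running 98th percentile, and a 200-ms refractory period.  Peak times are
    refined to the band-passed signal's local maximum.  A flat or empty
    signal yields an empty array.
    """
    x = np.asarray(ecg, dtype=np.float64)
    if rate < 250:
        raise ValueError("R-peak detection requires >= 250 Hz sampling")
    if x.size < int(rate) or np.ptp(x) == 0:
        return np.array([])
    sos = sps.butter(3, [5.0, 40.0], btype="bandpass", fs=rate, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(0.120 * rate))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    thresh = 0.25 * np.percentile(integ, 98)
    if thresh <= 0:
        return np.array([])
    refractory = int(0.200 * rate)
    cand, _ = sps.find_peaks(integ, height=thresh, distance=refractory)
    if cand.size == 0:
        return np.array([])
    # refine each detection to the nearby R-wave apex on the band-passed trace
    half = int(0.05 * rate)
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(bp[lo:hi])))
    peaks = np.asarray(sorted(set(peaks)))
    # re-enforce refractory after refinement
    kept = [peaks[0]]
    for p in peaks[1:]:
        if p - kept[-1] >= refractory:
            kept.append(p)
    return np.asarray(kept) / rate


def epochize(recording: Recording, detect_peaks_if_missing: bool = True) -> list[Epoch]:
    """Cut a recording into preprocessed 30-s epochs.

    ECG and respiration are Z-scored over the whole recording first; labels
    are merged; ``Unknown`` epochs are dropped; a trailing partial window is
    dropped.  R-peak times come from the recording when present, otherwise
    from :func:`detect_rpeaks` on the normalized ECG.
    """
    merged = merge_labels(recording.annotations["label"])
    ecg = zscore_normalize(recording.ecg) if recording.ecg is not None else None
    resp = zscore_normalize(recording.resp) if recording.resp is not None else None
    motion = (
        np.asarray(recording.motion, dtype=np.float64)
        if recording.motion is not None
        else None
    )

    r_times = recording.rpeak_times
    if r_times is None and ecg is not None and detect_peaks_if_missing:
        r_times = detect_rpeaks(ecg, recording.ecg_rate)

    n_full = recording.n_epochs
    for sig, rate in (
        (ecg, recording.ecg_rate),
        (resp, recording.resp_rate),
        (motion, recording.motion_rate),
    ):
        if sig is not None:
            n_full = min(n_full, int(len(sig) / (rate * EPOCH_S)))
    if recording.n_epochs - n_full > 1:
        raise ValueError("annotations exceed signal duration by more than one epoch")

    def sl(sig, rate, i):
        if sig is None:
            return None
        a = int(round(i * EPOCH_S * rate))
        return sig[a : a + int(round(EPOCH_S * rate))]

    epochs: list[Epoch] = []
    for row, label in zip(recording.annotations.itertuples(index=False), merged):
        i = int(row.epoch_index)
        if label == "Unknown" or i >= n_full:
            continue
        if label not in STATES:  # pragma: no cover — merge_labels guarantees this
            raise ValueError(f"unexpected merged label {label!r}")
        t0, t1 = i * EPOCH_S, (i + 1) * EPOCH_S
        rt = None
        if r_times is not None:
            rt = r_times[(r_times >= t0) & (r_times < t1)]
        epochs.append(
            Epoch(
                index=i,
                label=label,
                r_times=rt,
                ecg=sl(ecg, recording.ecg_rate, i),
                resp=sl(resp, recording.resp_rate, i),
                motion=sl(motion, recording.motion_rate, i),
                ecg_rate=recording.ecg_rate,
                resp_rate=recording.resp_rate,
                motion_rate=recording.motion_rate,
            )
        )
    return epochs


def preprocess_recording(recording: Recording) -> list[Epoch]:
    """Alias for :func:`epochize` — the full preprocessing entry point."""
    return epochize(recording)
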