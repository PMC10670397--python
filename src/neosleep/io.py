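"""Reading and writing multimodal recordings.

A recording bundles the signals the pipeline consumes for one subject:

* ECG at 500 Hz (optional — precomputed R-peak times may stand in for it),
* respiratory effort at 16 Hz,
* a video-derived motion-count trace at 8 Hz,
* per-epoch sleep-state annotations (30-s epochs) with labels from
  {AS, QS, Wake, Caretaking, Unknown}.

On disk a recording is a directory of plain-text files: one ``<channel>.csv``
per sampled channel (columns ``time,value``), ``rpeaks.csv`` (column ``time``)
when R-peak times are stored, ``annotations.csv`` (columns ``epoch_index,
onset_s,label``) and ``meta.json`` with subject id and sampling rates.
Floats are written with 17 significant digits so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ECG_RATE, EPOCH_S, MOTION_RATE, RESP_RATE

__all__ = ["Recording", "read_recording", "write_recording", "ANNOTATION_LABELS"]

#: Labels allowed in raw annotation files (before merging).
ANNOTATION_LABELS = frozenset({"AS", "QS", "Wake", "Caretaking", "CTW", "Unknown"})

_FLOAT_FMT = "%.17g"


@dataclass
class Recording:
    """One subject's multimodal recording plus per-epoch annotations."""

    subject_id: str
    annotations: pd.DataFrame  # columns: epoch_index, onset_s, label
    ecg: np.ndarray | None = None
    resp: np.ndarray | None = None
    motion: np.ndarray | None = None
    rpeak_times: np.ndarray | None = None  # seconds from recording start
    ecg_rate: float = ECG_RATE
    resp_rate: float = RESP_RATE
    motion_rate: float = MOTION_RATE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"epoch_index", "onset_s", "label"}
        if not required.issubset(self.annotations.columns):
            raise ValueError(f"annotations must have columns {sorted(required)}")
        bad = set(self.annotations["label"]) - ANNOTATION_LABELS
        if bad:
            raise ValueError(f"unrecognized annotation labels: {sorted(bad)}")
        durations = [
            len(sig) / rate
            for sig, rate in (
                (self.ecg, self.ecg_rate),
                (self.resp, self.resp_rate),
                (self.motion, self.motion_rate),
            )
            if sig is not None
        ]
        if durations and max(durations) - min(durations) > EPOCH_S:
            raise ValueError("channel durations disagree by more than one epoch")

    @property
    def n_epochs(self) -> int:
        return len(self.annotations)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * EPOCH_S

    def __eq__(self, other: object) -> bool:  # exact, for round-trip checks
        if not isinstance(other, Recording):
            return NotImplemented

        def eq_arr(a, b) -> bool:
            if a is None or b is None:
                return a is None and b is None
            return a.shape == b.shape and bool(np.all(a == b))

        return (
            self.subject_id == other.subject_id
            and self.annotations.reset_index(drop=True).equals(
                other.annotations.reset_index(drop=True)
            )
            and eq_arr(self.ecg, other.ecg)
            and eq_arr(self.resp, other.resp)
            and eq_arr(self.motion, other.motion)
            and eq_arr(self.rpeak_times, other.rpeak_times)
            and (self.ecg_rate, self.resp_rate, self.motion_rate)
            == (other.ecg_rate, other.resp_rate, other.motion_rate)
        )


def _write_channel(path: Path, values: np.ndarray, rate: float) -> None:
    t = np.arange(len(values)) / rate
    np.savetxt(
        path,
        np.column_stack([t, values]),
        delimiter=",",
        header="time,value",
        comments="",
        fmt=_FLOAT_FMT,
    )


def _read_channel(path: Path) -> np.ndarray:
    df = pd.read_csv(path, dtype={"value": np.float64}, float_precision="round_trip")
    return df["value"].to_numpy()


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write ``recording`` into directory ``path`` (created if missing)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": recording.subject_id,
        "ecg_rate": recording.ecg_rate,
        "resp_rate": recording.resp_rate,
        "motion_rate": recording.motion_rate,
        **recording.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    recording.annotations.to_csv(path / "annotations.csv", index=False)
    for name, sig, rate in (
        ("ecg", recording.ecg, recording.ecg_rate),
        ("resp", recording.resp, recording.resp_rate),
        ("motion", recording.motion, recording.motion_rate),
    ):
        if sig is not None:
            _write_channel(path / f"{name}.csv", np.asarray(sig, dtype=np.float64), rate)
    if recording.rpeak_times is not None:
        np.savetxt(
            path / "rpeaks.csv",
            np.asarray(recording.rpeak_times, dtype=np.float64),
            header="time",
            comments="",
            fmt=_FLOAT_FMT,
        )
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path / "meta.json"
    ann_path = path / "annotations.csv"
    if not meta_path.is_file():
        raise FileNotFoundError(f"missing metadata file: {meta_path}")
    if not ann_path.is_file():
        raise FileNotFoundError(f"missing annotation file: {ann_path}")
    meta = json.loads(meta_path.read_text())
    annotations = pd.read_csv(
        ann_path,
        dtype={"epoch_index": np.int64, "onset_s": np.float64, "label": str},
        float_precision="round_trip",
    )

    def maybe(name: str) -> np.ndarray | None:
        p = path / f"{name}.csv"
        return _read_channel(p) if p.is_file() else None

    rpeaks = None
    if (path / "rpeaks.csv").is_file():
        rpeaks = pd.read_csv(path / "rpeaks.csv", float_precision="round_trip")["time"].to_numpy()
    known = {"subject_id", "ecg_rate", "resp_rate", "motion_rate"}
    return Recording(
        subject_id=str(meta["subject_id"]),
        annotations=annotations,
        ecg=maybe("ecg"),
        resp=maybe("resp"),
        motion=maybe("motion"),
        rpeak_times=rpeaks,
        ecg_rate=float(meta["ecg_rate"]),
        resp_rate=float(meta["resp_rate"]),
        motion_rate=float(meta["motion_rate"]),
        meta={k: v for k, v in meta.items() if k not in known},
    )
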