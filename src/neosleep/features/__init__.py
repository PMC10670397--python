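"""Per-epoch feature extraction: 91 features in four families."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..io import Recording
from ..preprocess import preprocess_recording
from .cardiac import extract_cardiac
from .cri import extract_cri
from .motion import MotionEWMA, extract_motion
from .registry import FAMILIES, FEATURES, feature_names, write_registry_csv
from .respiratory import extract_respiratory

__all__ = [
    "extract_epoch_features",
    "extract_recording_features",
    "assemble_features",
    "feature_names",
    "FEATURES",
    "FAMILIES",
    "write_registry_csv",
]


def extract_epoch_features(epoch, ewma: MotionEWMA | None = None) -> dict[str, float]:
    """All 91 features of one preprocessed epoch, in registry order."""
    out: dict[str, float] = {}
    out.update(extract_cardiac(epoch))
    out.update(extract_respiratory(epoch))
    out.update(extract_cri(epoch))
    out.update(extract_motion(epoch, ewma=ewma))
    return {name: out[name] for name in feature_names()}


def extract_recording_features(recording: Recording) -> pd.DataFrame:
    """Feature matrix of one recording: one row per retained epoch.

    Columns: the 91 registry features plus ``label``, ``subject_id`` and
    ``epoch_index``.  Epochs are processed in temporal order so the motion
    EWMA state carries across the recording.
    """
    epochs = preprocess_recording(recording)
    ewma = MotionEWMA()
    rows = []
    for ep in epochs:
        row = extract_epoch_features(ep, ewma=ewma)
        row["label"] = ep.label
        row["subject_id"] = recording.subject_id
        row["epoch_index"] = ep.index
        rows.append(row)
    cols = feature_names() + ["label", "subject_id", "epoch_index"]
    return pd.DataFrame(rows, columns=cols)


def assemble_features(recordings: list[Recording]) -> pd.DataFrame:
    """Concatenate per-recording feature matrices into one cohort matrix.

    Raises on duplicate (subject, epoch) keys.  Missing values are left as
    NaN; imputation happens inside each cross-validation fold, fitted on the
    training partition only.
    """
    if not recordings:
        cols = feature_names() + ["label", "subject_id", "epoch_index"]
        return pd.DataFrame(columns=cols)
    df = pd.concat(
        [extract_recording_features(r) for r in recordings], ignore_index=True
    )
    dup = df.duplicated(subset=["subject_id", "epoch_index"])
    if dup.any():
        raise ValueError("duplicate subject/epoch keys in assembled matrix")
    assert not df["label"].isna().any() and not df["subject_id"].isna().any()
    return df
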