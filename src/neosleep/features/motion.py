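"""The 8 per-epoch motion (video-based actigraphy) features.

The pipeline consumes one scalar motion value per video frame (8 Hz, 240
samples per 30-s epoch).  When raw grayscale frames are available,
:func:`motion_from_frames` produces that series by thresholded 16x16-block
differencing: a frame's motion value is the number of blocks whose mean
absolute intensity change from the previous frame exceeds a threshold.  The
simulator emits the per-frame series directly, so the video front end is
optional.

``motion_count`` (number of nonzero samples per epoch) is smoothed across
the epoch sequence with an exponentially weighted moving average, so motion
extraction is stateful across consecutive epochs of one recording.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import Epoch
from .registry import feature_names

__all__ = [
    "motion_from_frames",
    "motion_epoch_features",
    "extract_motion",
    "MotionEWMA",
]

EPOCH_SAMPLES = 240  # 30 s at 8 Hz
DEFAULT_ALPHA = 0.3


def motion_from_frames(
    frames: np.ndarray, block: int = 16, threshold_frac: float = 0.02
) -> np.ndarray:
    """Per-frame motion values from a stack of grayscale frames.

    ``frames`` has shape (n_frames, height, width); partial border blocks are
    ignored.  The threshold is ``threshold_frac`` of the stack's dynamic
    range (max - min); a global intensity step below it produces zero motion.
    The first frame has no predecessor and scores 0.
    """
    f = np.asarray(frames, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("frames must be a (n, h, w) array")
    n, h, w = f.shape
    bh, bw = h // block, w // block
    if bh == 0 or bw == 0:
        raise ValueError(f"frames smaller than one {block}x{block} block")
    dyn = float(f.max() - f.min())
    thr = threshold_frac * dyn if dyn > 0 else np.inf
    out = np.zeros(n)
    trimmed = f[:, : bh * block, : bw * block]
    blocks = trimmed.reshape(n, bh, block, bw, block)
    means = np.abs(np.diff(blocks, axis=0)).mean(axis=(2, 4))  # (n-1, bh, bw)
    out[1:] = (means > thr).sum(axis=(1, 2))
    return out


class MotionEWMA:
    """Carries the smoothed motion count across consecutive epochs."""

    def __init__(self, alpha: float = DEFAULT_ALPHA) -> None:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        self.alpha = alpha
        self.smoothed: float | None = None

    def update(self, raw_count: float) -> float:
        if self.smoothed is None:
            self.smoothed = float(raw_count)
        else:
            self.smoothed = self.alpha * raw_count + (1 - self.alpha) * self.smoothed
        return self.smoothed


def motion_epoch_features(
    series: np.ndarray, ewma: MotionEWMA | None = None
) -> dict[str, float]:
    """The 8 motion features of one 240-sample epoch series.

    ``ewma`` holds the smoothing state from the previous epoch; when omitted
    the raw nonzero count is reported unsmoothed.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size != EPOCH_SAMPLES:
        raise ValueError(f"expected {EPOCH_SAMPLES} samples, got {x.size}")
    raw_count = float(np.count_nonzero(x > 0))
    count = ewma.update(raw_count) if ewma is not None else raw_count
    p25, p50, p75, p95 = np.percentile(x, [25, 50, 75, 95])
    return {
        "motion_mean": float(x.mean()),
        "motion_sd": float(x.std()),
        "motion_sum": float(x.sum()),
        "motion_count": count,
        "motion_p25": float(p25),
        "motion_p50": float(p50),
        "motion_p75": float(p75),
        "motion_p95": float(p95),
    }


def extract_motion(epoch: Epoch, ewma: MotionEWMA | None = None) -> dict[str, float]:
    """The 8 motion features of one preprocessed epoch, in registry order."""
    out = {name: np.nan for name in feature_names("motion")}
    if epoch.motion is None:
        return out
    out.update(motion_epoch_features(epoch.motion, ewma=ewma))
    return out
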