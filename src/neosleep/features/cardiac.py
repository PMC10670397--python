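"""The 34 per-epoch cardiac features.

Sources: the R-peak times falling in the epoch (HRV features) and the
Z-scored ECG trace (line-length and ECG Lempel-Ziv features).  Intervals
outside a physiological range are flagged as artefacts and excluded from all
HRV statistics (NN = the retained "normal-to-normal" intervals).  Missing
values (too few beats, undefined entropies) propagate as NaN — imputation is
the modeling stage's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..entropy import lempel_ziv, quadratic_sampen, sample_entropy, sampen_auc
from ..preprocess import Epoch
from .registry import feature_names

__all__ = [
    "RRSeries",
    "rr_from_rpeaks",
    "hrv_band_powers",
    "line_length_features",
    "hr_decelerations",
    "extract_cardiac",
    "HRV_BANDS",
]

#: Default HRV band edges in Hz.  Neonatal heart rates reach 2.5-3 Hz, so the
#: analyzed range extends to 2 Hz with the two extended high-frequency bands.
HRV_BANDS = {
    "vlf": (0.01, 0.04),
    "lf": (0.04, 0.2),
    "hf": (0.2, 1.0),
    "shf": (1.0, 1.5),
    "uhf": (1.5, 2.0),
}

#: Physiological RR range for preterm infants (80-300 bpm), milliseconds.
DEFAULT_RR_RANGE = (200.0, 750.0)


@dataclass
class RRSeries:
    """Inter-beat intervals within one epoch.

    ``rr`` holds all successive differences in ms; ``valid`` flags intervals
    inside the physiological range; ``nn`` are the retained intervals used by
    every HRV statistic.
    """

    r_times: np.ndarray  # seconds
    rr: np.ndarray  # ms, len = len(r_times) - 1
    valid: np.ndarray  # bool mask over rr

    @property
    def nn(self) -> np.ndarray:
        return self.rr[self.valid]

    @property
    def nn_times(self) -> np.ndarray:
        """Interval end times (s) of the retained intervals."""
        return self.r_times[1:][self.valid]


def rr_from_rpeaks(
    r_times: np.ndarray, rr_range: tuple[float, float] = DEFAULT_RR_RANGE
) -> RRSeries:
    """Successive R-peak differences in ms, with out-of-range flagging."""
    t = np.asarray(r_times, dtype=np.float64)
    if t.size < 2:
        return RRSeries(t, np.array([]), np.array([], dtype=bool))
    if np.any(np.diff(t) <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    rr = np.diff(t) * 1000.0
    valid = (rr >= rr_range[0]) & (rr <= rr_range[1])
    return RRSeries(t, rr, valid)


def hrv_band_powers(
    rr: RRSeries, bands: dict[str, tuple[float, float]] = HRV_BANDS, fs: float = 4.0
) -> dict[str, float]:
    """Welch band powers of the RR tachogram.

    The NN series is linearly interpolated to a uniform ``fs`` grid over its
    time span, mean-detrended, and integrated (trapezoid) over each band.
    Also returns ``total`` (power over the full analyzed range) and the
    ``lf_hf`` ratio.  All values NaN with fewer than 8 valid intervals.
    """
    names = list(bands) + ["total", "lf_hf"]
    nn = rr.nn
    if nn.size < 8:
        return {k: np.nan for k in names}
    t = rr.nn_times
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    if grid.size < 8:
        return {k: np.nan for k in names}
    x = np.interp(grid, t, nn)
    x = x - x.mean()
    nperseg = min(256, x.size)
    # zero-padded FFT so the narrow VLF band holds enough bins to integrate
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, nfft=2048)
    lo = min(b[0] for b in bands.values())
    hi = max(b[1] for b in bands.values())

    def band_power(a: float, b: float) -> float:
        m = (f >= a) & (f < b)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(pxx[m], f[m]))

    out = {k: band_power(*edges) for k, edges in bands.items()}
    out["total"] = band_power(lo, hi)
    out["lf_hf"] = (
        out["lf"] / out["hf"] if "lf" in out and "hf" in out and out["hf"] > 0 else np.nan
    )
    return out


def line_length_features(
    ecg: np.ndarray, rate: float, subwindow_s: float = 1.0
) -> tuple[float, float, float]:
    """(total line length, mean, SD) of |x[k+1]-x[k]| over the epoch.

    Mean and SD are taken over line lengths of non-overlapping ``subwindow_s``
    sub-windows.
    """
    x = np.asarray(ecg, dtype=np.float64)
    if x.size < 2:
        return np.nan, np.nan, np.nan
    diffs = np.abs(np.diff(x))
    total = float(diffs.sum())
    w = int(round(subwindow_s * rate))
    n_win = x.size // w
    if n_win < 1:
        return total, total, 0.0
    sub = np.array(
        [np.abs(np.diff(x[i * w : (i + 1) * w])).sum() for i in range(n_win)]
    )
    return total, float(sub.mean()), float(sub.std())


def hr_decelerations(
    rr: RRSeries, theta: float = 0.1, baseline_window: int = 15, min_run: int = 2
) -> tuple[float, float]:
    """Fraction of beats inside deceleration runs and their mean magnitude.

    The baseline is a running median of the NN series (window
    ``baseline_window`` beats); a deceleration is a maximal run of at least
    ``min_run`` beats with ``NN >= (1 + theta) * baseline``.  Magnitude is
    the mean over runs of the maximal fractional RR excess.  A series with
    no decelerations returns (0, 0).
    """
    nn = rr.nn
    if nn.size < 5:
        return np.nan, np.nan
    if not np.isfinite(theta):
        return 0.0, 0.0
    k = min(baseline_window, nn.size if nn.size % 2 == 1 else nn.size - 1)
    if k % 2 == 0:
        k -= 1
    baseline = sps.medfilt(nn, kernel_size=k)
    # medfilt zero-pads the borders; repair them with the interior median
    half = k // 2
    if half > 0:
        baseline[:half] = np.median(nn[: k])
        baseline[-half:] = np.median(nn[-k:])
    above = nn >= (1.0 + theta) * baseline
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, nn.size))
    runs = [(a, b) for a, b in runs if b - a >= min_run]
    if not runs:
        return 0.0, 0.0
    n_decel_beats = sum(b - a for a, b in runs)
    mags = [float(np.max(nn[a:b] / baseline[a:b] - 1.0)) for a, b in runs]
    return n_decel_beats / nn.size, float(np.mean(mags))


def _safe_sampen(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    if x.size <= m + 1:
        return np.nan
    sd = x.std()
    if sd == 0:
        return 0.0
    return sample_entropy(x, m=m, r=r_frac * sd)


def extract_cardiac(epoch: Epoch) -> dict[str, float]:
    """The 34 cardiac features of one preprocessed epoch, in registry order."""
    out = {name: np.nan for name in feature_names("cardiac")}
    r_times = epoch.r_times if epoch.r_times is not None else np.array([])
    out["beats_per_epoch"] = float(len(r_times))

    if epoch.ecg is not None and len(epoch.ecg) >= 2:
        ll, ll_mean, ll_sd = line_length_features(epoch.ecg, epoch.ecg_rate)
        out["ecg_line_length"] = ll
        out["ecg_line_length_mean"] = ll_mean
        out["ecg_line_length_sd"] = ll_sd
        # LZ on the 500-Hz trace counts mostly noise crossings; decimate to
        # ~125 Hz (anti-aliased, still > 2x the 40-Hz QRS band) first.
        q = max(1, int(epoch.ecg_rate // 125))
        ecg_dec = sps.decimate(epoch.ecg, q) if q > 1 else np.asarray(epoch.ecg)
        out["lz_ecg"] = lempel_ziv(ecg_dec, normalize=True)

    rr = rr_from_rpeaks(r_times)
    nn = rr.nn
    if nn.size >= 2:
        dnn = np.diff(nn)
        out["nn_mean"] = float(nn.mean())
        out["nn_median"] = float(np.median(nn))
        out["nn_sdnn"] = float(nn.std(ddof=1))
        out["nn_min"] = float(nn.min())
        out["nn_max"] = float(nn.max())
        out["nn_range"] = float(np.ptp(nn))
        out["nn_cv"] = float(nn.std(ddof=1) / nn.mean())
        hr = 60000.0 / nn
        out["hr_mean"] = float(hr.mean())
        out["hr_sd"] = float(hr.std(ddof=1)) if hr.size >= 2 else np.nan
        out["hr_min"] = float(hr.min())
        out["hr_max"] = float(hr.max())
        if dnn.size >= 1:
            out["nn_rmssd"] = float(np.sqrt(np.mean(dnn**2)))
            out["nn_pnn10"] = float(np.mean(np.abs(dnn) > 10.0))
            out["nn_pnn20"] = float(np.mean(np.abs(dnn) > 20.0))
            out["nn_pnn50"] = float(np.mean(np.abs(dnn) > 50.0))
        if dnn.size >= 2:
            out["nn_sdsd"] = float(dnn.std(ddof=1))
        out["lz_hrv"] = lempel_ziv(nn, normalize=True) if nn.size >= 2 else np.nan

    powers = hrv_band_powers(rr)
    out["hrv_vlf_power"] = powers["vlf"]
    out["hrv_lf_power"] = powers["lf"]
    out["hrv_hf_power"] = powers["hf"]
    out["hrv_shf_power"] = powers["shf"]
    out["hrv_uhf_power"] = powers["uhf"]
    out["hrv_total_power"] = powers["total"]
    out["hrv_lf_hf_ratio"] = powers["lf_hf"]

    out["decel_pct"], out["decel_mag"] = hr_decelerations(rr)

    if nn.size > 3:
        sd = nn.std()
        out["hrv_sampen"] = _safe_sampen(nn)
        if sd > 0:
            out["hrv_sampen_auc"] = sampen_auc(nn)
            out["hrv_qse"] = quadratic_sampen(nn, r=0.2 * sd)
    return out
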