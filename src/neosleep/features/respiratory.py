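"""The 41 per-epoch respiratory features.

All features derive from the Z-scored respiratory-effort signal.  Breath
segmentation (alternating peaks and troughs) underlies the rate, amplitude
and flow/volume families; "volume" and "flow" are effort-signal proxies —
chest impedance is uncalibrated, so they carry no physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ..entropy import approx_entropy, sample_entropy
from ..preprocess import Epoch
from .registry import feature_names

__all__ = [
    "BreathSegmentation",
    "segment_breaths",
    "rate_features",
    "breath_correlation",
    "resp_spectral_features",
    "amplitude_features",
    "flow_volume_features",
    "resp_regularity",
    "extract_respiratory",
    "RESP_BANDS",
]

#: Respiratory spectral band edges in Hz.
RESP_BANDS = {"vlf": (0.01, 0.05), "lf": (0.05, 0.15), "hf": (0.15, 0.5)}


@dataclass
class BreathSegmentation:
    """Alternating extrema of the effort signal and the derived breaths.

    A breath spans trough ``i`` -> peak ``i`` -> trough ``i+1``; there are
    ``n_breaths = len(trough_times) - 1`` complete breaths when at least two
    troughs bracket a peak.
    """

    peak_times: np.ndarray
    peak_vals: np.ndarray
    trough_times: np.ndarray
    trough_vals: np.ndarray
    # per complete breath:
    periods: np.ndarray = field(default_factory=lambda: np.array([]))
    inhale_dur: np.ndarray = field(default_factory=lambda: np.array([]))
    exhale_dur: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))  # peak - trough

    @property
    def n_breaths(self) -> int:
        return len(self.periods)


def _alternate(
    p_idx: np.ndarray, t_idx: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Enforce peak/trough alternation, keeping the larger of same-type runs."""
    events = [(i, "p") for i in p_idx] + [(i, "t") for i in t_idx]
    events.sort()
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = x[idx] > x[prev] if kind == "p" else x[idx] < x[prev]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    peaks = np.array([i for i, k in kept if k == "p"], dtype=np.int64)
    troughs = np.array([i for i, k in kept if k == "t"], dtype=np.int64)
    return peaks, troughs


def segment_breaths(
    resp: np.ndarray,
    rate: float,
    min_prominence_frac: float = 0.2,
    min_period_s: float = 0.5,
) -> BreathSegmentation:
    """Segment the effort signal into breaths via prominence-filtered extrema.

    Minimum prominence defaults to 0.2 x the epoch SD; same-type extrema
    closer than ``min_period_s`` are suppressed; alternation is enforced by
    keeping the more extreme of two consecutive same-type extrema.  A flat
    signal yields an empty segmentation.
    """
    x = np.asarray(resp, dtype=np.float64)
    empty = BreathSegmentation(*(np.array([]) for _ in range(4)))
    if x.size < int(2 * rate) or np.ptp(x) == 0:
        return empty
    prom = min_prominence_frac * x.std()
    dist = max(1, int(min_period_s * rate))
    p_idx, _ = sps.find_peaks(x, prominence=prom, distance=dist)
    t_idx, _ = sps.find_peaks(-x, prominence=prom, distance=dist)
    if p_idx.size == 0 or t_idx.size == 0:
        return empty
    p_idx, t_idx = _alternate(p_idx, t_idx, x)
    t = np.arange(x.size) / rate
    seg = BreathSegmentation(
        peak_times=t[p_idx],
        peak_vals=x[p_idx],
        trough_times=t[t_idx],
        trough_vals=x[t_idx],
    )
    # complete breaths: trough -> peak -> next trough
    periods, inh, exh, amps = [], [], [], []
    for i in range(len(t_idx) - 1):
        between = p_idx[(p_idx > t_idx[i]) & (p_idx < t_idx[i + 1])]
        if between.size != 1:
            continue
        pk = between[0]
        periods.append(t[t_idx[i + 1]] - t[t_idx[i]])
        inh.append(t[pk] - t[t_idx[i]])
        exh.append(t[t_idx[i + 1]] - t[pk])
        amps.append(x[pk] - x[t_idx[i]])
    seg.periods = np.asarray(periods)
    seg.inhale_dur = np.asarray(inh)
    seg.exhale_dur = np.asarray(exh)
    seg.amplitudes = np.asarray(amps)
    return seg


def rate_features(seg: BreathSegmentation) -> dict[str, float]:
    """Variance/median/SD of instantaneous frequency, log bpm, |df|/dt."""
    keys = ["freq_var", "freq_median", "freq_sd", "log_bpm", "freq_rel_change"]
    if seg.n_breaths < 3:
        return {k: np.nan for k in keys}
    f = 1.0 / seg.periods
    df = np.abs(np.diff(f))
    return {
        "freq_var": float(f.var(ddof=1)),
        "freq_median": float(np.median(f)),
        "freq_sd": float(f.std(ddof=1)),
        "log_bpm": float(np.log(60.0 * f.mean())),
        "freq_rel_change": float(np.mean(df / seg.periods[:-1])),
    }


def breath_correlation(
    resp: np.ndarray, rate: float, seg: BreathSegmentation, resample_n: int = 40
) -> dict[str, float]:
    """Pearson correlations of consecutive breaths resampled to a common length."""
    keys = ["corr_mean", "corr_sd", "corr_min", "corr_max"]
    if seg.n_breaths < 3 or len(seg.trough_times) < 3:
        return {k: np.nan for k in keys}
    x = np.asarray(resp, dtype=np.float64)
    t = np.arange(x.size) / rate
    shapes = []
    for i in range(len(seg.trough_times) - 1):
        grid = np.linspace(seg.trough_times[i], seg.trough_times[i + 1], resample_n)
        shapes.append(np.interp(grid, t, x))
    cors = []
    for a, b in zip(shapes[:-1], shapes[1:]):
        if a.std() == 0 or b.std() == 0:
            continue
        cors.append(float(np.corrcoef(a, b)[0, 1]))
    if len(cors) < 2:
        return {k: np.nan for k in keys}
    cors = np.asarray(cors)
    return {
        "corr_mean": float(cors.mean()),
        "corr_sd": float(cors.std(ddof=1)),
        "corr_min": float(cors.min()),
        "corr_max": float(cors.max()),
    }


def resp_spectral_features(
    resp: np.ndarray, rate: float, bands: dict[str, tuple[float, float]] = RESP_BANDS
) -> dict[str, float]:
    """Welch-spectrum features: band log/normalized powers, ratios, dominant peak."""
    x = np.asarray(resp, dtype=np.float64)
    keys = (
        [f"log_power_{b}" for b in bands]
        + [f"norm_power_{b}" for b in bands]
        + ["vlf_hf_ratio", "lf_hf_ratio", "total_power", "dominant_freq", "log_dominant_power"]
    )
    if x.size < 64 or np.ptp(x) == 0:
        return {k: np.nan for k in keys}
    # zero-pad the FFT so the VLF band (0.01-0.05 Hz) contains bins; a 30-s
    # window cannot truly resolve it, so VLF power reflects spectral leakage
    # of the slowest resolvable content
    f, pxx = sps.welch(x - x.mean(), fs=rate, nperseg=min(256, x.size), nfft=4096)

    def band_power(a: float, b: float) -> float:
        m = (f >= a) & (f < b)
        return float(np.trapezoid(pxx[m], f[m])) if m.sum() >= 2 else 0.0

    bp = {b: band_power(*e) for b, e in bands.items()}
    part_total = sum(bp.values())
    out: dict[str, float] = {}
    for b in bands:
        out[f"log_power_{b}"] = float(np.log(bp[b])) if bp[b] > 0 else np.nan
        out[f"norm_power_{b}"] = bp[b] / part_total if part_total > 0 else np.nan
    out["vlf_hf_ratio"] = bp["vlf"] / bp["hf"] if bp.get("hf", 0) > 0 else np.nan
    out["lf_hf_ratio"] = bp["lf"] / bp["hf"] if bp.get("hf", 0) > 0 else np.nan
    analyzed = (f >= 0.01) & (f <= rate / 2)
    out["total_power"] = float(np.trapezoid(pxx[analyzed], f[analyzed]))
    dom = np.argmax(np.where(analyzed, pxx, -np.inf))
    out["dominant_freq"] = float(f[dom])
    out["log_dominant_power"] = float(np.log(pxx[dom])) if pxx[dom] > 0 else np.nan
    return out


def amplitude_features(seg: BreathSegmentation, epoch_sd: float) -> dict[str, float]:
    """Standardized extremum medians, extremum ApEn, peak-to-trough stats."""
    keys = [
        "peak_median_std",
        "trough_median_std",
        "peak_apen",
        "trough_apen",
        "p2t_median",
        "log_p2t_ratio_median",
        "log_p2t_ratio_sd",
    ]
    out = {k: np.nan for k in keys}
    if seg.n_breaths < 2 or epoch_sd == 0:
        return out
    out["peak_median_std"] = float(np.median(seg.peak_vals) / epoch_sd)
    out["trough_median_std"] = float(np.median(seg.trough_vals) / epoch_sd)
    for name, vals in (("peak_apen", seg.peak_vals), ("trough_apen", seg.trough_vals)):
        if vals.size >= 4:
            sd = vals.std()
            out[name] = approx_entropy(vals, m=1, r=0.2 * sd) if sd > 0 else 0.0
    out["p2t_median"] = float(np.median(seg.amplitudes))
    # log peak/|trough| per breath; skip breaths with non-positive operands
    ratios = []
    for i in range(len(seg.trough_times) - 1):
        m = (seg.peak_times > seg.trough_times[i]) & (seg.peak_times < seg.trough_times[i + 1])
        if m.sum() != 1:
            continue
        pk = float(seg.peak_vals[m][0])
        tr = abs(float(seg.trough_vals[i]))
        if pk > 0 and tr > 0:
            ratios.append(np.log(pk / tr))
    if len(ratios) >= 2:
        r = np.asarray(ratios)
        out["log_p2t_ratio_median"] = float(np.median(r))
        out["log_p2t_ratio_sd"] = float(r.std(ddof=1))
    return out


def flow_volume_features(
    resp: np.ndarray, rate: float, seg: BreathSegmentation
) -> dict[str, float]:
    """Effort-integral volume proxies, limb flow proxies and their ratios."""
    keys = [
        "volume_cycle_median",
        "volume_inhale_median",
        "volume_exhale_median",
        "flow_cycle_median",
        "flow_inhale_median",
        "flow_exhale_median",
        "ie_time_ratio",
        "ie_flow_ratio",
        "ie_time_ratio_breathwise",
        "ie_flow_ratio_breathwise",
        "amp_ratio_mean",
        "amp_ratio_sd",
        "amp_ratio_delta",
    ]
    out = {k: np.nan for k in keys}
    if seg.n_breaths < 2:
        return out
    x = np.asarray(resp, dtype=np.float64)
    t = np.arange(x.size) / rate

    def limb_integral(t0: float, t1: float, baseline: float) -> float:
        m = (t >= t0) & (t <= t1)
        if m.sum() < 2:
            return np.nan
        return float(np.trapezoid(np.abs(x[m] - baseline), t[m]))

    vol_in, vol_ex, vol_cycle = [], [], []
    flow_in, flow_ex, flow_cycle = [], [], []
    bi = 0
    for i in range(len(seg.trough_times) - 1):
        m = (seg.peak_times > seg.trough_times[i]) & (seg.peak_times < seg.trough_times[i + 1])
        if m.sum() != 1:
            continue
        t0, t1 = seg.trough_times[i], seg.trough_times[i + 1]
        tp = float(seg.peak_times[m][0])
        pk = float(seg.peak_vals[m][0])
        vi = limb_integral(t0, tp, float(seg.trough_vals[i]))
        ve = limb_integral(tp, t1, float(seg.trough_vals[i + 1]))
        if np.isnan(vi) or np.isnan(ve):
            bi += 1
            continue
        vol_in.append(vi)
        vol_ex.append(ve)
        vol_cycle.append(vi + ve)
        flow_in.append((pk - float(seg.trough_vals[i])) / seg.inhale_dur[bi])
        flow_ex.append((pk - float(seg.trough_vals[i + 1])) / seg.exhale_dur[bi])
        flow_cycle.append(seg.amplitudes[bi] / seg.periods[bi])
        bi += 1
    if len(vol_cycle) < 2:
        return out
    out["volume_cycle_median"] = float(np.median(vol_cycle))
    out["volume_inhale_median"] = float(np.median(vol_in))
    out["volume_exhale_median"] = float(np.median(vol_ex))
    out["flow_cycle_median"] = float(np.median(flow_cycle))
    out["flow_inhale_median"] = float(np.median(flow_in))
    out["flow_exhale_median"] = float(np.median(flow_ex))
    med_in, med_ex = np.median(seg.inhale_dur), np.median(seg.exhale_dur)
    out["ie_time_ratio"] = float(med_in / med_ex) if med_ex > 0 else np.nan
    mfi, mfe = np.median(flow_in), np.median(flow_ex)
    out["ie_flow_ratio"] = float(mfi / mfe) if mfe > 0 else np.nan
    ok = seg.exhale_dur > 0
    if ok.sum() >= 2:
        out["ie_time_ratio_breathwise"] = float(
            np.median(seg.inhale_dur[ok] / seg.exhale_dur[ok])
        )
    fi, fe = np.asarray(flow_in), np.asarray(flow_ex)
    ok = fe > 0
    if ok.sum() >= 2:
        out["ie_flow_ratio_breathwise"] = float(np.median(fi[ok] / fe[ok]))
    amps = seg.amplitudes
    prev_ok = amps[:-1] > 0
    if prev_ok.sum() >= 1:
        ratio = amps[1:][prev_ok] / amps[:-1][prev_ok]
        out["amp_ratio_mean"] = float(ratio.mean())
        out["amp_ratio_sd"] = float(ratio.std(ddof=1)) if ratio.size >= 2 else 0.0
        out["amp_ratio_delta"] = float(ratio[-1] - ratio[0])
    return out


def resp_regularity(resp: np.ndarray, rate: float, target_rate: float = 2.0) -> float:
    """SampEn (m=2, r=0.2 SD) of the effort signal downsampled to 2 Hz."""
    x = np.asarray(resp, dtype=np.float64)
    step = max(1, int(round(rate / target_rate)))
    ds = x[::step]
    if ds.size < 4:
        return np.nan
    sd = ds.std()
    if sd == 0:
        return 0.0
    return sample_entropy(ds, m=2, r=0.2 * sd)


def extract_respiratory(epoch: Epoch) -> dict[str, float]:
    """The 41 respiratory features of one preprocessed epoch, registry order."""
    out = {name: np.nan for name in feature_names("respiratory")}
    if epoch.resp is None or len(epoch.resp) < 2:
        return out
    resp, rate = np.asarray(epoch.resp, dtype=np.float64), epoch.resp_rate
    seg = segment_breaths(resp, rate)

    for k, v in rate_features(seg).items():
        out[f"resp_{k}"] = v
    for k, v in breath_correlation(resp, rate, seg).items():
        out[f"resp_{k}"] = v
    for k, v in resp_spectral_features(resp, rate).items():
        out[f"resp_{k}"] = v
    for k, v in amplitude_features(seg, float(resp.std())).items():
        out[f"resp_{k}"] = v
    for k, v in flow_volume_features(resp, rate, seg).items():
        out[f"resp_{k}"] = v
    out["resp_sampen"] = resp_regularity(resp, rate)
    return out
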