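"""Canonical registry of the 91 per-epoch features.

Four families: 34 cardiac, 41 respiratory, 8 cardiorespiratory-interaction
(CRI) and 8 motion features.  The registry fixes the feature names, order and
family membership that every extractor and the assembled feature matrix must
follow; it can be exported as a machine-readable CSV.

Where the published feature inventory is enumerable from the methods text the
names below mirror it; the cardiac family is completed to its 34-slot budget
with standard time-domain HRV statistics over the NN (normal-to-normal)
intervals and instantaneous heart rate, and the respiratory family to its
41-slot budget with the breath-wise variants of the inhale:exhale time- and
flow-ratio features.  Each filler is individually named so its identity is
auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "FeatureDef",
    "FEATURES",
    "feature_names",
    "FAMILIES",
    "write_registry_csv",
]

FAMILIES = ("cardiac", "respiratory", "cri", "motion")


@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str
    description: str
    units: str


def _f(name: str, family: str, description: str, units: str = "-") -> FeatureDef:
    return FeatureDef(name, family, description, units)


_CARDIAC = [
    _f("beats_per_epoch", "cardiac", "Number of R peaks in the epoch", "count"),
    _f("hrv_vlf_power", "cardiac", "HRV spectral power, VLF band (0.01-0.04 Hz)", "ms^2"),
    _f("hrv_lf_power", "cardiac", "HRV spectral power, LF band (0.04-0.2 Hz)", "ms^2"),
    _f("hrv_hf_power", "cardiac", "HRV spectral power, HF band (0.2-1.0 Hz)", "ms^2"),
    _f("hrv_shf_power", "cardiac", "HRV spectral power, extended sHF band (1.0-1.5 Hz)", "ms^2"),
    _f("hrv_uhf_power", "cardiac", "HRV spectral power, extended uHF band (1.5-2.0 Hz)", "ms^2"),
    _f("hrv_total_power", "cardiac", "HRV spectral power over 0.01-2.0 Hz", "ms^2"),
    _f("hrv_lf_hf_ratio", "cardiac", "LF power / HF power"),
    _f("ecg_line_length", "cardiac", "Sum of absolute sample-to-sample ECG differences", "z"),
    _f("ecg_line_length_mean", "cardiac", "Mean line length over 1-s ECG sub-windows", "z"),
    _f("ecg_line_length_sd", "cardiac", "SD of line length over 1-s ECG sub-windows", "z"),
    _f("decel_pct", "cardiac", "Fraction of beats inside HR-deceleration runs"),
    _f("decel_mag", "cardiac", "Mean maximal RR excess ratio over deceleration runs"),
    _f("hrv_sampen", "cardiac", "Sample entropy of NN intervals (m=2, r=0.2 SD)", "nat"),
    _f("hrv_sampen_auc", "cardiac", "Trapezoidal area of SampEn over r/SD in 0.10-0.30", "nat*ms"),
    _f("hrv_qse", "cardiac", "Quadratic sample entropy: SampEn + ln(2r)", "nat"),
    _f("lz_ecg", "cardiac", "Normalized LZ76 complexity of the median-binarized ECG"),
    _f("lz_hrv", "cardiac", "Normalized LZ76 complexity of the median-binarized NN series"),
    _f("nn_mean", "cardiac", "Mean NN interval", "ms"),
    _f("nn_median", "cardiac", "Median NN interval", "ms"),
    _f("nn_sdnn", "cardiac", "SD of NN intervals (SDNN)", "ms"),
    _f("nn_rmssd", "cardiac", "Root mean square of successive NN differences", "ms"),
    _f("nn_sdsd", "cardiac", "SD of successive NN differences", "ms"),
    _f("nn_cv", "cardiac", "Coefficient of variation of NN intervals"),
    _f("nn_pnn10", "cardiac", "Fraction of successive NN differences > 10 ms"),
    _f("nn_pnn20", "cardiac", "Fraction of successive NN differences > 20 ms"),
    _f("nn_pnn50", "cardiac", "Fraction of successive NN differences > 50 ms"),
    _f("nn_min", "cardiac", "Minimum NN interval", "ms"),
    _f("nn_max", "cardiac", "Maximum NN interval", "ms"),
    _f("nn_range", "cardiac", "Range of NN intervals", "ms"),
    _f("hr_mean", "cardiac", "Mean instantaneous heart rate", "bpm"),
    _f("hr_sd", "cardiac", "SD of instantaneous heart rate", "bpm"),
    _f("hr_min", "cardiac", "Minimum instantaneous heart rate", "bpm"),
    _f("hr_max", "cardiac", "Maximum instantaneous heart rate", "bpm"),
]

_RESPIRATORY = [
    _f("resp_freq_var", "respiratory", "Variance of instantaneous breathing frequency", "Hz^2"),
    _f("resp_freq_median", "respiratory", "Median instantaneous breathing frequency", "Hz"),
    _f("resp_freq_sd", "respiratory", "SD of instantaneous breathing frequency", "Hz"),
    _f("resp_log_bpm", "respiratory", "Log of breaths per minute", "log(1/min)"),
    _f("resp_freq_rel_change", "respiratory", "Mean |df|/dt between successive breaths", "Hz/s"),
    _f("resp_corr_mean", "respiratory", "Mean breath-by-breath correlation"),
    _f("resp_corr_sd", "respiratory", "SD of breath-by-breath correlations"),
    _f("resp_corr_min", "respiratory", "Minimum breath-by-breath correlation"),
    _f("resp_corr_max", "respiratory", "Maximum breath-by-breath correlation"),
    _f("resp_log_power_vlf", "respiratory", "Log spectral power, VLF band (0.01-0.05 Hz)"),
    _f("resp_log_power_lf", "respiratory", "Log spectral power, LF band (0.05-0.15 Hz)"),
    _f("resp_log_power_hf", "respiratory", "Log spectral power, HF band (0.15-0.5 Hz)"),
    _f("resp_norm_power_vlf", "respiratory", "VLF power / (VLF+LF+HF) power"),
    _f("resp_norm_power_lf", "respiratory", "LF power / (VLF+LF+HF) power"),
    _f("resp_norm_power_hf", "respiratory", "HF power / (VLF+LF+HF) power"),
    _f("resp_vlf_hf_ratio", "respiratory", "VLF power / HF power"),
    _f("resp_lf_hf_ratio", "respiratory", "LF power / HF power"),
    _f("resp_total_power", "respiratory", "Spectral power over 0.01 Hz to Nyquist", "z^2"),
    _f("resp_dominant_freq", "respiratory", "Frequency of the spectral maximum", "Hz"),
    _f("resp_log_dominant_power", "respiratory", "Log power at the dominant frequency"),
    _f("resp_peak_median_std", "respiratory", "Median peak amplitude / epoch SD"),
    _f("resp_trough_median_std", "respiratory", "Median trough amplitude / epoch SD"),
    _f("resp_peak_apen", "respiratory", "ApEn of the peak-amplitude sequence (m=1)", "nat"),
    _f("resp_trough_apen", "respiratory", "ApEn of the trough-amplitude sequence (m=1)", "nat"),
    _f("resp_p2t_median", "respiratory", "Median peak-to-trough amplitude", "z"),
    _f("resp_log_p2t_ratio_median", "respiratory", "Median log(peak/|trough|) per breath"),
    _f("resp_log_p2t_ratio_sd", "respiratory", "SD of log(peak/|trough|) per breath"),
    _f("resp_volume_cycle_median", "respiratory", "Median effort-integral over a breath cycle", "z*s"),
    _f("resp_volume_inhale_median", "respiratory", "Median effort-integral over the inhale limb", "z*s"),
    _f("resp_volume_exhale_median", "respiratory", "Median effort-integral over the exhale limb", "z*s"),
    _f("resp_flow_cycle_median", "respiratory", "Median amplitude/period over breath cycles", "z/s"),
    _f("resp_flow_inhale_median", "respiratory", "Median inhale amplitude/duration", "z/s"),
    _f("resp_flow_exhale_median", "respiratory", "Median exhale amplitude/duration", "z/s"),
    _f("resp_ie_time_ratio", "respiratory", "Median inhale time / median exhale time"),
    _f("resp_ie_flow_ratio", "respiratory", "Median inhale flow / median exhale flow"),
    _f("resp_ie_time_ratio_breathwise", "respiratory", "Median per-breath inhale:exhale time ratio"),
    _f("resp_ie_flow_ratio_breathwise", "respiratory", "Median per-breath inhale:exhale flow ratio"),
    _f("resp_amp_ratio_mean", "respiratory", "Mean successive breath-amplitude ratio"),
    _f("resp_amp_ratio_sd", "respiratory", "SD of successive breath-amplitude ratios"),
    _f("resp_amp_ratio_delta", "respiratory", "Last minus first successive amplitude ratio"),
    _f("resp_sampen", "respiratory", "SampEn of the effort signal at 2 Hz (m=2, r=0.2 SD)", "nat"),
]

_CRI = [
    _f("cri_vg_degree_mean", "cri", "Mean degree of the CRI visibility graph"),
    _f("cri_vg_degree_sd", "cri", "SD of CRI visibility-graph degrees"),
    _f("cri_dvg_degree_mean", "cri", "Mean degree of the differenced-CRI visibility graph"),
    _f("cri_dvg_degree_sd", "cri", "SD of differenced-CRI visibility-graph degrees"),
    _f("cri_assortativity", "cri", "Degree assortativity of the CRI visibility graph"),
    _f("cri_cc_mean", "cri", "Mean local clustering coefficient of the CRI VG"),
    _f("cri_cc_sd", "cri", "SD of local clustering coefficients of the CRI VG"),
    _f("cri_degree_sampen", "cri", "SampEn of the VG degree sequence in temporal order", "nat"),
]

_MOTION = [
    _f("motion_mean", "motion", "Mean motion amplitude within the epoch", "counts"),
    _f("motion_sd", "motion", "SD of motion amplitude within the epoch", "counts"),
    _f("motion_sum", "motion", "Sum of motion amplitude within the epoch", "counts"),
    _f("motion_count", "motion", "EWMA-smoothed number of nonzero motion samples", "count"),
    _f("motion_p25", "motion", "25th percentile of epoch motion values", "counts"),
    _f("motion_p50", "motion", "50th percentile of epoch motion values", "counts"),
    _f("motion_p75", "motion", "75th percentile of epoch motion values", "counts"),
    _f("motion_p95", "motion", "95th percentile of epoch motion values", "counts"),
]

FEATURES: tuple[FeatureDef, ...] = tuple(_CARDIAC + _RESPIRATORY + _CRI + _MOTION)

_EXPECTED = {"cardiac": 34, "respiratory": 41, "cri": 8, "motion": 8}
for fam, count in _EXPECTED.items():
    actual = sum(f.family == fam for f in FEATURES)
    assert actual == count, f"{fam} registry has {actual} features, expected {count}"
assert len({f.name for f in FEATURES}) == len(FEATURES) == 91


def feature_names(family: str | None = None) -> list[str]:
    """Names in registry order, optionally restricted to one family."""
    if family is not None and family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return [f.name for f in FEATURES if family is None or f.family == family]


def write_registry_csv(path: str | Path) -> Path:
    """Export the registry as CSV (name, family, description, units)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "family", "description", "units"])
        for f in FEATURES:
            w.writerow([f.name, f.family, f.description, f.units])
    return path
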