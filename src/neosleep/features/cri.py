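"""The 8 cardiorespiratory-interaction (CRI) features.

The CRI series samples the (Z-scored) respiratory-effort amplitude at each
R-peak time, giving an unevenly sampled beat-by-beat series that couples the
two modalities.  Its structure is summarized through natural visibility
graphs: degree statistics of the VG and of the differenced-series VG (DVG),
degree assortativity, local clustering, and the sample entropy of the degree
sequence.  The real R-peak times serve as the VG time axis by default, since
the CRI is intrinsically unevenly sampled; index mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import Epoch
from ..visibility import (
    VisibilityGraph,
    assortativity,
    clustering_statistics,
    degree_sample_entropy,
    degree_statistics,
    differencing_visibility_graph,
    natural_visibility_graph,
)
from .registry import feature_names

__all__ = ["CRISeries", "build_cri", "extract_cri"]


@dataclass
class CRISeries:
    """Respiratory amplitude sampled at R-peak times within one epoch."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def build_cri(
    r_times: np.ndarray, resp: np.ndarray, resp_rate: float, t_offset: float = 0.0
) -> CRISeries:
    """Interpolate the respiratory signal at each R-peak time.

    ``t_offset`` is the absolute time of the first respiration sample (the
    epoch start); R times outside the signal's span are dropped.
    """
    rt = np.asarray(r_times, dtype=np.float64)
    x = np.asarray(resp, dtype=np.float64)
    grid = t_offset + np.arange(x.size) / resp_rate
    inside = (rt >= grid[0]) & (rt <= grid[-1])
    rt = rt[inside]
    return CRISeries(times=rt, values=np.interp(rt, grid, x))


def _vg_features(series: CRISeries, use_times: bool = True) -> dict[str, float]:
    t = series.times if use_times else None
    vg: VisibilityGraph = natural_visibility_graph(series.values, t)
    dvg = differencing_visibility_graph(series.values, t)
    d_mean, d_sd = degree_statistics(vg)
    dd_mean, dd_sd = degree_statistics(dvg)
    cc_mean, cc_sd = clustering_statistics(vg)
    return {
        "cri_vg_degree_mean": d_mean,
        "cri_vg_degree_sd": d_sd,
        "cri_dvg_degree_mean": dd_mean,
        "cri_dvg_degree_sd": dd_sd,
        "cri_assortativity": assortativity(vg),
        "cri_cc_mean": cc_mean,
        "cri_cc_sd": cc_sd,
        "cri_degree_sampen": degree_sample_entropy(vg),
    }


def extract_cri(epoch: Epoch, use_times: bool = True) -> dict[str, float]:
    """The 8 CRI features of one preprocessed epoch, in registry order.

    All values are missing when the epoch holds fewer than 4 R peaks or no
    respiration channel.
    """
    out = {name: np.nan for name in feature_names("cri")}
    if (
        epoch.r_times is None
        or len(epoch.r_times) < 4
        or epoch.resp is None
        or len(epoch.resp) < 2
    ):
        return out
    series = build_cri(epoch.r_times, epoch.resp, epoch.resp_rate, t_offset=epoch.start_s)
    if len(series) < 4:
        return out
    out.update(_vg_features(series, use_times=use_times))
    return out
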