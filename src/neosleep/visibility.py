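"""Natural visibility graphs of (possibly unevenly sampled) time series.

The natural visibility graph (VG) maps a series ``(t_i, y_i)`` to a simple
undirected graph on nodes ``0..n-1`` in temporal order: nodes ``a < b`` are
linked iff every intermediate sample lies strictly below the straight line
from ``(t_a, y_a)`` to ``(t_b, y_b)``.  Collinear intermediates block
visibility (strict criterion), so a linear series maps to a path graph.
Consecutive samples are always mutually visible, giving every VG a connected
path backbone.  The criterion compares slopes only, so the graph is invariant
under positive affine transforms of the values and uniform rescaling of the
time axis.

The DVG is the VG of the first-differenced series; differencing whitens the
slow trends that dominate natural visibility, exposing beat-to-beat
irregularity instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entropy import sample_entropy

__all__ = [
    "VisibilityGraph",
    "natural_visibility_graph",
    "differencing_visibility_graph",
    "degree_statistics",
    "assortativity",
    "clustering_statistics",
    "degree_sample_entropy",
]


@dataclass
class VisibilityGraph:
    """Simple undirected graph; nodes ``0..n-1`` in temporal order."""

    n: int
    edges: frozenset[tuple[int, int]]  # each edge (a, b) with a < b
    _degrees: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def degrees(self) -> np.ndarray:
        if self._degrees is None:
            d = np.zeros(self.n, dtype=np.int64)
            for a, b in self.edges:
                d[a] += 1
                d[b] += 1
            self._degrees = d
        return self._degrees

    def adjacency_sets(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n)]
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj


def natural_visibility_graph(
    values: np.ndarray, times: np.ndarray | None = None
) -> VisibilityGraph:
    """Build the strict natural visibility graph of a series.

    ``times`` defaults to the sample index.  O(n^2): for each anchor ``a``
    the running maximum of the slope to intermediate samples decides
    visibility of each later node in one pass.
    """
    y = np.asarray(values, dtype=np.float64).ravel()
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    t = np.arange(n, dtype=np.float64) if times is None else np.asarray(times, np.float64)
    if t.size != n:
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    edges: set[tuple[int, int]] = set()
    for a in range(n - 1):
        edges.add((a, a + 1))
        max_slope = (y[a + 1] - y[a]) / (t[a + 1] - t[a])
        for b in range(a + 2, n):
            slope = (y[b] - y[a]) / (t[b] - t[a])
            if slope > max_slope:
                edges.add((a, b))
            max_slope = max(max_slope, slope)
    return VisibilityGraph(n=n, edges=frozenset(edges))


def differencing_visibility_graph(
    values: np.ndarray, times: np.ndarray | None = None
) -> VisibilityGraph:
    """VG of the first-differenced series (values ``y[i+1]-y[i]`` at ``t[i+1]``)."""
    y = np.asarray(values, dtype=np.float64).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 samples to difference")
    dy = np.diff(y)
    dt = None if times is None else np.asarray(times, np.float64)[1:]
    return natural_visibility_graph(dy, dt)


def degree_statistics(g: VisibilityGraph) -> tuple[float, float]:
    """Mean and population SD of the degree sequence."""
    d = g.degrees.astype(np.float64)
    return float(d.mean()), float(d.std())


def assortativity(g: VisibilityGraph) -> float:
    """Newman degree assortativity: Pearson correlation of degrees over edges.

    Both orientations of each edge are counted.  NaN when the graph has
    fewer than 2 edges or zero degree variance over edge endpoints (e.g. a
    complete graph).
    """
    if len(g.edges) < 2:
        return np.nan
    d = g.degrees
    pairs = np.array([(d[a], d[b]) for a, b in g.edges], dtype=np.float64)
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    vx = x.std()
    if vx == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (vx * y.std()))


def clustering_statistics(g: VisibilityGraph) -> tuple[float, float]:
    """Mean and population SD of the local clustering coefficient.

    Local CC of a node = realized triangles / possible neighbor pairs;
    defined as 0 for nodes of degree < 2.
    """
    if g.n < 3:
        raise ValueError("need at least 3 nodes")
    adj = g.adjacency_sets()
    cc = np.zeros(g.n)
    for v in range(g.n):
        nb = adj[v]
        k = len(nb)
        if k < 2:
            continue
        links = sum(len(adj[u] & nb) for u in nb) // 2
        cc[v] = links / (k * (k - 1) / 2)
    return float(cc.mean()), float(cc.std())


def degree_sample_entropy(g: VisibilityGraph, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn of the degree sequence in temporal node order.

    Tolerance is ``r_frac * SD(degrees)``; a regular graph (zero degree
    variance) is maximally ordered and returns 0 by convention.
    """
    d = g.degrees.astype(np.float64)
    if d.size <= m + 1:
        return np.nan
    sd = d.std()
    if sd == 0:
        return 0.0
    return sample_entropy(d, m=m, r=r_frac * sd)
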