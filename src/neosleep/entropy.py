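"""Nonlinear signal-regularity measures: SampEn, ApEn and Lempel-Ziv.

These primitives are shared across the cardiac, respiratory and
cardiorespiratory-interaction feature families.  Conventions:

* **Sample entropy** follows Richman & Moorman: ``SampEn(m, r) = -ln(A/B)``
  where ``B`` counts pairs of length-``m`` templates and ``A`` pairs of
  length-``m+1`` templates within Chebyshev distance ``< r`` (strict),
  self-matches excluded, both counts taken over the first ``N - m``
  templates.  Undefined (NaN) when either count is zero.
* **Approximate entropy** follows Pincus: self-matches included, distance
  ``<= r``, ``ApEn = Phi_m - Phi_{m+1}`` with ``Phi_m`` the mean log match
  frequency.
* **Lempel-Ziv complexity** is the LZ76 exhaustive-history phrase count of
  the median-binarized series (values strictly above the median map to 1).
  A constant series of length >= 2 parses into two phrases (the first symbol
  is always novel; the remainder is one reproducible phrase).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "sample_entropy",
    "approx_entropy",
    "sampen_auc",
    "quadratic_sampen",
    "lempel_ziv",
    "lz76_phrase_count",
    "binarize_by_median",
]


def _template_pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(A, B): template-pair match counts at lengths m+1 and m (strict < r)."""
    n = x.size
    n_templ = n - m  # both lengths use the first n - m templates
    tm = sliding_window_view(x, m)[:n_templ]
    tm1 = sliding_window_view(x, m + 1)[:n_templ]
    # pairwise Chebyshev distances, upper triangle only
    dm = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    dm1 = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    iu = np.triu_indices(n_templ, k=1)
    b = int(np.count_nonzero(dm[iu] < r))
    a = int(np.count_nonzero(dm1[iu] < r))
    return a, b


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy of a 1-D series.

    ``r`` defaults to ``0.2 * SD(series)``.  Returns NaN when the series is
    too short (``len <= m + 1``), when ``r`` is not positive (e.g. a constant
    series with the default ``r``), or when either template count is zero.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size <= m + 1:
        return np.nan
    if r is None:
        r = 0.2 * x.std()
    if not r > 0:
        raise ValueError("tolerance r must be positive")
    a, b = _template_pair_counts(x, m, r)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def approx_entropy(series: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Approximate entropy (self-matches included, distance <= r)."""
    x = np.asarray(series, dtype=np.float64).ravel()
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * x.std()
    if r < 0:
        raise ValueError("tolerance r must be non-negative")

    def phi(mm: int) -> float:
        templ = sliding_window_view(x, mm)
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        c = np.count_nonzero(d <= r, axis=1) / templ.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen_auc(
    series: np.ndarray, m: int = 2, r_grid: np.ndarray | None = None
) -> float:
    """Trapezoidal integral of ``SampEn(r)`` over a tolerance grid.

    ``r_grid`` defaults to ``SD * {0.10, 0.15, 0.20, 0.25, 0.30}``; it must be
    increasing with at least 3 points.  NaN if any grid point yields an
    undefined SampEn.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if r_grid is None:
        sd = x.std()
        if sd == 0:
            return np.nan
        r_grid = sd * np.array([0.10, 0.15, 0.20, 0.25, 0.30])
    r_grid = np.asarray(r_grid, dtype=np.float64)
    if r_grid.size < 3 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be increasing with >= 3 points")
    vals = np.array([sample_entropy(x, m, r) for r in r_grid])
    if np.any(np.isnan(vals)):
        return np.nan
    return float(np.trapezoid(vals, r_grid))


def quadratic_sampen(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Quadratic sample entropy: ``SampEn(m, r) + ln(2r)``."""
    x = np.asarray(series, dtype=np.float64).ravel()
    if r is None:
        sd = x.std()
        if sd == 0:
            return np.nan
        r = 0.2 * sd
    se = sample_entropy(x, m, r)
    return float(se + np.log(2.0 * r)) if np.isfinite(se) else np.nan


def binarize_by_median(series: np.ndarray) -> np.ndarray:
    """0/1 sequence: 1 where the value exceeds the series median."""
    x = np.asarray(series, dtype=np.float64).ravel()
    return (x > np.median(x)).astype(np.uint8)


def lz76_phrase_count(bits) -> int:
    """LZ76 exhaustive-history phrase count of a 0/1 sequence.

    Parsing: the next phrase is the shortest prefix of the unparsed remainder
    that cannot be copied from the history (any start position strictly
    before the phrase start; the copy may overlap the phrase itself).  The
    final phrase counts even if it is reproducible.  Uses ``bytes.find`` so
    the scan runs at C speed.
    """
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.size == 0:
        raise ValueError("empty sequence")
    if np.any(arr > 1):
        raise ValueError("sequence must be binary")
    s = arr.tobytes()
    n = len(s)
    c = 0
    i = 0
    while i < n:
        l = 1
        # grow the phrase while s[i:i+l] can be copied from a start < i
        while i + l <= n and s.find(s[i : i + l], 0, i + l - 1) != -1:
            l += 1
        c += 1
        i += l
    return c


def lempel_ziv(series: np.ndarray, normalize: bool = False) -> float:
    """Lempel-Ziv complexity of a real-valued series.

    The series is binarized at its median, then parsed with LZ76.  With
    ``normalize=True`` the phrase count ``c`` is scaled by ``log2(n) / n``,
    the asymptotic phrase rate of a random binary sequence, making values
    comparable across epoch lengths.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    c = lz76_phrase_count(binarize_by_median(x))
    if not normalize:
        return float(c)
    n = x.size
    return float(c * np.log2(n) / n)
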