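"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the mathematical definition, with
nested loops and no shared code with the package, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_brute(x, m: int, r: float) -> float:
    """Sample entropy by exhaustive template comparison (Richman-Moorman)."""
    x = list(map(float, x))
    n = len(x)
    n_templ = n - m

    def count(length: int) -> int:
        c = 0
        for i in range(n_templ):
            for j in range(i + 1, n_templ):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) < r:
                    c += 1
        return c

    a, b = count(m + 1), count(m)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def apen_brute(x, m: int, r: float) -> float:
    """Approximate entropy by exhaustive counting (self-matches included)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            c = 0
            for j in range(nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def lz76_brute(bits) -> int:
    """LZ76 phrase count by scanning every history start position."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        l = 1
        while i + l <= n:
            # is s[i:i+l] reproducible from a start strictly before i?
            found = any(s[p : p + l] == s[i : i + l] for p in range(i))
            if not found:
                break
            l += 1
        c += 1
        i += l
    return c


def vg_edges_brute(values, times=None) -> set[tuple[int, int]]:
    """Natural-visibility edge set by testing every intermediate point."""
    y = list(map(float, values))
    n = len(y)
    t = list(range(n)) if times is None else list(map(float, times))
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            visible = True
            for c in range(a + 1, b):
                line = y[b] + (y[a] - y[b]) * (t[b] - t[c]) / (t[b] - t[a])
                if not y[c] < line:
                    visible = False
                    break
            if visible:
                edges.add((a, b))
    return edges


def kappa_brute(cm) -> float:
    """Cohen's kappa evaluated directly from p_o and p_e."""
    cm = [list(map(float, row)) for row in cm]
    total = sum(sum(row) for row in cm)
    p_o = sum(cm[i][i] for i in range(len(cm))) / total
    p_e = 0.0
    for i in range(len(cm)):
        row = sum(cm[i])
        col = sum(cm[j][i] for j in range(len(cm)))
        p_e += row * col / total**2
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def auc_pair_count(scores_pos, scores_neg) -> float:
    """AUC as the exhaustive fraction of correctly ordered pairs (ties = 1/2)."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


def assortativity_brute(edges, n) -> float:
    """Newman assortativity from the edge list via explicit degree pairs."""
    deg = [0] * n
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    xs, ys = [], []
    for a, b in edges:
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (xs.std() * ys.std()))


def clustering_brute(edges, n) -> tuple[float, float]:
    """Local clustering coefficients by explicit triangle enumeration."""
    adj = [set() for _ in range(n)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    cc = []
    for v in range(n):
        nb = sorted(adj[v])
        k = len(nb)
        if k < 2:
            cc.append(0.0)
            continue
        tri = 0
        for i in range(k):
            for j in range(i + 1, k):
                if nb[j] in adj[nb[i]]:
                    tri += 1
        cc.append(tri / (k * (k - 1) / 2))
    cc = np.asarray(cc)
    return float(cc.mean()), float(cc.std())
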