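"""Independent brute-force oracles for the test suite.

Everything here is written from first principles (python loops, explicit
shortest-path enumeration) and deliberately avoids networkx/scipy graph
routines so that it can serve as an independent cross-check of the package's
graph metrics and statistics.
"""

from __future__ import annotations

import math

import numpy as np

INF = math.inf


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_clustering(adj: np.ndarray) -> float:
    """Mean of 2*t_i / (k_i (k_i - 1)); degree < 2 contributes 0."""
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        t = sum(adj[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1:])
        total += 2.0 * t / (k * (k - 1))
    return total / n


def bf_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    s = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
            if i != j and d[i, j] < INF)
    return s / (n * (n - 1))


def bf_char_path_length(adj: np.ndarray) -> float:
    """Mean distance over connected ordered pairs; NaN when no edges."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and d[i, j] < INF]
    return float(np.mean(vals)) if vals else float("nan")


def bf_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = bf_global_efficiency(sub)
    return out


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized by (n-1)(n-2) over ordered pairs, via explicit
    shortest-path counting (BFS path-count dynamic programming)."""
    n = adj.shape[0]
    if n < 3:
        return np.zeros(n)
    d = floyd_warshall(adj)
    # sigma[s, t]: number of shortest s-t paths
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted((t for t in range(n) if d[s, t] < INF), key=lambda t: d[s, t])
        for t in order:
            if t == s:
                continue
            sigma[s, t] = sum(sigma[s, u] for u in range(n)
                              if adj[u, t] and d[s, u] == d[s, t] - 1)
    bc = np.zeros(n)
    for h in range(n):
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if i == j or i == h or j == h:
                    continue
                if d[i, j] == INF or sigma[i, j] == 0:
                    continue
                if d[i, h] + d[h, j] == d[i, j]:
                    acc += sigma[i, h] * sigma[h, j] / sigma[i, j]
        bc[h] = acc / ((n - 1) * (n - 2))
    return bc


def bf_bh_reject(pvals, q) -> np.ndarray:
    """Benjamini-Hochberg step-up by exhaustive check over all ranks."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def bf_pearson(x, y) -> float:
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def tone_amplitude(x: np.ndarray, fs: float, f: float) -> float:
    """Amplitude of the component at frequency f via direct projection."""
    t = np.arange(x.size) / fs
    c = np.cos(2 * np.pi * f * t)
    s = np.sin(2 * np.pi * f * t)
    return 2.0 * math.hypot(float(x @ c), float(x @ s)) / x.size
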