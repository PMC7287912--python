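"""Independent oracles for graph indexes and the signed-rank test.

Everything here is deliberately naive: simple-path enumeration for
distances and path counts, direct neighbor-pair counting for clustering,
and explicit 2^m sign-assignment enumeration for the Wilcoxon test. These
share no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def all_simple_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    n = adj.shape[0]
    paths = []

    def extend(path, visited):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for w in range(n):
            if adj[v, w] and w not in visited:
                path.append(w)
                visited.add(w)
                extend(path, visited)
                path.pop()
                visited.remove(w)

    extend([s], {s})
    return paths


def brute_distances_and_counts(adj: np.ndarray):
    """(distance matrix, shortest-path count matrix, shortest path lists)."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.zeros((n, n))
    shortest: dict[tuple[int, int], list[list[int]]] = {}
    for s in range(n):
        counts[s, s] = 1.0
        for t in range(n):
            if t == s:
                continue
            paths = all_simple_paths(adj, s, t)
            if not paths:
                shortest[(s, t)] = []
                continue
            d = min(len(p) - 1 for p in paths)
            best = [p for p in paths if len(p) - 1 == d]
            dist[s, t] = d
            counts[s, t] = len(best)
            shortest[(s, t)] = best
    return dist, counts, shortest


def brute_degree(adj):
    return adj.sum(axis=1)


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nbrs, 2))
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_nodal_apl(adj: np.ndarray) -> np.ndarray:
    dist, _, _ = brute_distances_and_counts(adj)
    n = adj.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        finite = [dist[i, j] for j in range(n) if j != i and math.isfinite(dist[i, j])]
        if finite:
            out[i] = float(np.mean(finite))
    return out


def brute_cpl(adj: np.ndarray) -> float:
    dist, _, _ = brute_distances_and_counts(adj)
    n = adj.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(i + 1, n) if math.isfinite(dist[i, j])]
    return float(np.mean(vals))


def brute_global_efficiency(adj: np.ndarray) -> np.ndarray:
    dist, _, _ = brute_distances_and_counts(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / dist[i, j] for j in range(n) if j != i and math.isfinite(dist[i, j]))
        out[i] /= n - 1
    return out


def brute_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        dist, _, _ = brute_distances_and_counts(sub)
        total = sum(
            1.0 / dist[a, b]
            for a in range(k)
            for b in range(k)
            if a != b and math.isfinite(dist[a, b])
        )
        out[i] = total / (k * (k - 1))
    return out


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    _, counts, shortest = brute_distances_and_counts(adj)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = shortest[(s, t)]
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                out[v] += through / len(paths)
    return out


def brute_wilcoxon_two_sided(pre, post) -> tuple[float, float]:
    """Exact two-sided signed-rank p by explicit 2^m sign enumeration.

    Drops zero differences, ranks |d| with mid-ranks, W = rank sum of
    positive differences; p = fraction of sign assignments whose rank sum
    is at least as far from the null mean as the observed W.
    """
    from scipy.stats import rankdata

    d = np.asarray(post, float) - np.asarray(pre, float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product((0, 1), repeat=m):
        w = sum(r for r, sgn in zip(ranks, signs) if sgn)
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return float(w_obs), count / 2**m
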