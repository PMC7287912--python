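"""Nodal and global graph indexes on binary undirected graphs.

Implements, from first principles, the six indexes used for the pre/post
network comparison: degree, clustering coefficient, nodal average path
length, local efficiency, nodal global efficiency, and betweenness
centrality (Brandes' algorithm), plus the network-level characteristic path
length used by the small-worldness ratio.

Disconnected graphs are routine at low connection densities, so path-length
statistics average over reachable pairs only and efficiency-type indexes
use 1/inf = 0 (the standard connectome convention); the nodal average path
length of an isolated node is NaN and excluded from statistics downstream.
"""

from __future__ import annotations

import warnings
from collections import deque
from typing import Optional, Union

import numpy as np
import pandas as pd

from .connectivity import BinaryGraph

__all__ = [
    "degree",
    "clustering_coefficient",
    "shortest_path_lengths",
    "nodal_average_path_length",
    "characteristic_path_length",
    "nodal_global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "nodal_metric_table",
    "NODAL_METRICS",
]

#: Metric names, in the column order of :func:`nodal_metric_table`.
NODAL_METRICS = (
    "degree",
    "clustering_coefficient",
    "average_path_length",
    "local_efficiency",
    "global_efficiency",
    "betweenness_centrality",
)

GraphLike = Union[BinaryGraph, np.ndarray]


def _adjacency(g: GraphLike) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return g.adjacency
    return BinaryGraph(adjacency=np.asarray(g)).adjacency


def _neighbor_lists(adj: np.ndarray) -> list[list[int]]:
    return [np.flatnonzero(adj[i]).tolist() for i in range(adj.shape[0])]


def degree(g: GraphLike) -> np.ndarray:
    """Per-node edge counts (row sums of the adjacency matrix)."""
    return _adjacency(g).sum(axis=1).astype(np.int64)


def clustering_coefficient(g: GraphLike) -> np.ndarray:
    """Fraction of each node's neighbor pairs that are themselves connected.

    c_i = 2 t_i / (k_i (k_i - 1)), with t_i the number of triangles through
    node i; defined as 0 for nodes with degree < 2.
    """
    adj = _adjacency(g).astype(np.float64)
    k = adj.sum(axis=1)
    triangles = np.diag(adj @ adj @ adj) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c


def shortest_path_lengths(g: GraphLike) -> np.ndarray:
    """All-pairs shortest-path hop counts via breadth-first search.

    Returns an N x N float matrix with zero diagonal; unreachable pairs are
    ``np.inf``.
    """
    adj = _adjacency(g)
    n = adj.shape[0]
    nbrs = _neighbor_lists(adj)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        d = dist[s]
        d[s] = 0.0
        q = deque([s])
        while q:
            v = q.popleft()
            dv = d[v]
            for w in nbrs[v]:
                if np.isinf(d[w]):
                    d[w] = dv + 1.0
                    q.append(w)
    return dist


def nodal_average_path_length(
    g: GraphLike, node: Optional[int] = None, *, dist: Optional[np.ndarray] = None
) -> Union[float, np.ndarray]:
    """Mean hop distance from a node to its reachable peers.

    Unreachable peers are excluded from the mean. An isolated node (no
    reachable peer) gets NaN with a warning; callers drop NaN entries from
    group statistics.
    """
    if dist is None:
        dist = shortest_path_lengths(g)
    n = dist.shape[0]
    off = dist.copy()
    np.fill_diagonal(off, np.nan)
    finite = np.isfinite(off)
    counts = finite.sum(axis=1)
    if np.any(counts == 0):
        warnings.warn(
            f"isolated node(s) {np.flatnonzero(counts == 0).tolist()}: "
            "average path length undefined (NaN)"
        )
    with np.errstate(invalid="ignore"):
        apl = np.where(counts > 0, np.nansum(np.where(finite, off, 0.0), axis=1), np.nan)
        apl = apl / np.where(counts > 0, counts, 1)
    return apl if node is None else float(apl[node])


def characteristic_path_length(g: GraphLike, *, dist: Optional[np.ndarray] = None) -> float:
    """Mean shortest-path length over all reachable unordered node pairs."""
    if dist is None:
        dist = shortest_path_lengths(g)
    iu, ju = np.triu_indices(dist.shape[0], k=1)
    d = dist[iu, ju]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("graph has no edges: characteristic path length undefined")
    return float(d[finite].mean())


def nodal_global_efficiency(
    g: GraphLike, node: Optional[int] = None, *, dist: Optional[np.ndarray] = None
) -> Union[float, np.ndarray]:
    """Mean inverse shortest-path distance from a node to every peer.

    Unreachable peers contribute 0 (1/inf); an isolated node scores 0.
    Values lie in [0, 1].
    """
    if dist is None:
        dist = shortest_path_lengths(g)
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    return eff if node is None else float(eff[node])


def local_efficiency(g: GraphLike, node: Optional[int] = None) -> Union[float, np.ndarray]:
    """Global efficiency of the subgraph induced by a node's neighbors.

    The node itself is excluded from its neighborhood subgraph; nodes with
    fewer than two neighbors score 0.
    """
    adj = _adjacency(g)
    n = adj.shape[0]
    nodes = range(n) if node is None else [node]
    out = np.zeros(n)
    for i in nodes:
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        dsub = shortest_path_lengths(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / dsub
        np.fill_diagonal(inv, 0.0)
        out[i] = inv.sum() / (k * (k - 1))
    return out if node is None else float(out[node])


def betweenness_centrality(g: GraphLike, normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness of every node (Brandes' algorithm, exact).

    For node v: sum over unordered pairs {s, t} (s != t != v) of the
    fraction of shortest s-t paths passing through v. Unnormalized by
    default; with ``normalized=True`` values are divided by (N-1)(N-2)/2.
    """
    adj = _adjacency(g)
    n = adj.shape[0]
    nbrs = _neighbor_lists(adj)
    bc = np.zeros(n)
    for s in range(n):
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            stack.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair visited from both endpoints
    if normalized:
        if n > 2:
            bc /= (n - 1) * (n - 2) / 2.0
        else:
            bc[:] = 0.0
    return bc


def nodal_metric_table(
    g: BinaryGraph,
    *,
    normalized_betweenness: bool = False,
) -> pd.DataFrame:
    """All six nodal indexes of a graph as a (ROI x metric) DataFrame."""
    dist = shortest_path_lengths(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # isolated-node NaN handled downstream
        apl = nodal_average_path_length(g, dist=dist)
    table = pd.DataFrame(
        {
            "degree": degree(g),
            "clustering_coefficient": clustering_coefficient(g),
            "average_path_length": apl,
            "local_efficiency": local_efficiency(g),
            "global_efficiency": nodal_global_efficiency(g, dist=dist),
            "betweenness_centrality": betweenness_centrality(g, normalized=normalized_betweenness),
        }
    )
    if g.roi_set is not None:
        table.index = pd.Index(g.roi_set.labels, name="roi")
    else:
        table.index.name = "node"
    return table
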