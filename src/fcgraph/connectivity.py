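"""Functional connectivity estimation and proportional density thresholding.

A subject-session ROI time-series matrix (volumes x ROIs) is reduced to a
symmetric node-by-node Pearson correlation matrix with zero diagonal, then
binarized by keeping the strongest E = round(density * N(N-1)/2) edges so
that every subject's graph has the same connection density before metrics
are compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .rois import RoiSet

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesSession",
    "ConnectivityMatrix",
    "BinaryGraph",
    "pearson_matrix",
    "fisher_z",
    "threshold_to_density",
    "edge_count_for_density",
]


@dataclass
class TimeSeriesSession:
    """One subject-session BOLD matrix (volumes x ROIs)."""

    subject: str
    session: Literal["pre", "post"]
    data: np.ndarray
    tr: float = 3.0
    roi_set: Optional[RoiSet] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x ROIs)")
        if self.session not in ("pre", "post"):
            raise ValueError(f"session must be 'pre' or 'post', got {self.session!r}")
        if self.roi_set is not None and self.data.shape[1] != self.roi_set.n:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but ROI set has {self.roi_set.n} labels"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI association matrix with zero diagonal."""

    values: np.ndarray
    roi_set: Optional[RoiSet] = None
    kind: Literal["pearson", "fisher_z"] = "pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at a fixed connection density."""

    adjacency: np.ndarray
    density_target: Optional[float] = None
    roi_set: Optional[RoiSet] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        """Realized edge density E / (N(N-1)/2)."""
        n = self.n
        return self.n_edges / (n * (n - 1) / 2)

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))


def pearson_matrix(ts: TimeSeriesSession) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI time courses, zero diagonal.

    Raises
    ------
    ValueError
        If fewer than 3 volumes, or any ROI column has zero variance
        (the offending ROI is named).
    """
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError(f"need >= 3 volumes to estimate correlations, got {data.shape[0]}")
    variances = data.var(axis=0)
    zero = np.flatnonzero(variances == 0)
    if zero.size:
        labels = (
            [ts.roi_set.labels[i] for i in zero] if ts.roi_set is not None else zero.tolist()
        )
        raise ValueError(f"zero-variance ROI column(s): {labels}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, roi_set=ts.roi_set, kind="pearson")


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entry-wise Fisher r-to-z transform (arctanh) of a Pearson matrix.

    Off-diagonal entries with |r| = 1 are clipped to 1 - 1e-7 with a warning.
    """
    if m.kind != "pearson":
        raise ValueError(f"fisher_z expects a pearson matrix, got kind={m.kind!r}")
    r = m.values.copy()
    mask = ~np.eye(m.n, dtype=bool)
    if np.any(np.abs(r[mask]) >= 1.0):
        warnings.warn("correlations with |r| = 1 clipped to 1 - 1e-7 before arctanh")
        r[mask] = np.clip(r[mask], -1.0 + 1e-7, 1.0 - 1e-7)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, roi_set=m.roi_set, kind="fisher_z")


def edge_count_for_density(n: int, density_target: float) -> int:
    """Number of edges kept at a nominal density: round-half-up, minimum 1."""
    n_pairs = n * (n - 1) // 2
    return max(1, int(np.floor(density_target * n_pairs + 0.5)))


def threshold_to_density(
    m: ConnectivityMatrix,
    density_target: float,
    ranking: Literal["signed", "absolute"] = "signed",
) -> BinaryGraph:
    """Binarize a connectivity matrix by keeping its strongest edges.

    The E = round(density_target * N(N-1)/2) top-ranked node pairs (minimum
    one edge) become edges. Ranking is by signed weight descending by default
    (strongest positive correlations first); ``ranking="absolute"`` ranks by
    magnitude. Ties are broken lexicographically on the (i, j) index pair,
    which makes the edge ranking a deterministic total order — consequently
    edge sets are nested across densities.
    """
    if not 0.0 < density_target <= 1.0:
        raise ValueError(f"density_target must be in (0, 1], got {density_target}")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"ranking must be 'signed' or 'absolute', got {ranking!r}")
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    w = m.values[iu, ju]
    key = np.abs(w) if ranking == "absolute" else w
    # stable sort on (-weight, i, j): lexsort's last key dominates
    order = np.lexsort((ju, iu, -key))
    n_edges = edge_count_for_density(n, density_target)
    if n_edges < len(order) and key[order[n_edges - 1]] == key[order[n_edges]]:
        logger.warning(
            "ties at the density cutoff (weight %g at density %.2f); "
            "lexicographic tie-break applied",
            key[order[n_edges - 1]],
            density_target,
        )
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density_target=density_target, roi_set=m.roi_set)
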