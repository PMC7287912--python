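"""scikit-learn-style transformers over the per-stage operations.

These wrap the module-level functions so the stages compose with sklearn
pipelines and model selection. A "sample" is one subject-session: the
input to `ConnectivityTransformer` is a sequence of (volumes x ROIs)
arrays, which becomes a stack of connectivity matrices, then a stack of
binary adjacencies, then a flat (samples x features) nodal-metric matrix.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .connectivity import (
    BinaryGraph,
    ConnectivityMatrix,
    TimeSeriesSession,
    fisher_z,
    pearson_matrix,
    threshold_to_density,
)
from .metrics import NODAL_METRICS, nodal_metric_table

__all__ = ["ConnectivityTransformer", "DensityThreshold", "GraphMetricsExtractor"]


class ConnectivityTransformer(BaseEstimator, TransformerMixin):
    """Pearson connectivity matrices from stacked ROI time series.

    Parameters
    ----------
    use_fisher_z : bool, default False
        Apply the Fisher r-to-z transform entry-wise after correlation.

    Attributes
    ----------
    n_rois_ : int
        Number of ROIs seen during fit.
    """

    def __init__(self, use_fisher_z: bool = False):
        self.use_fisher_z = use_fisher_z

    def fit(self, X: Sequence[np.ndarray], y=None):
        X = self._validate(X)
        self.n_rois_ = X[0].shape[1]
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "n_rois_")
        X = self._validate(X)
        out = []
        for series in X:
            if series.shape[1] != self.n_rois_:
                raise ValueError(
                    f"expected {self.n_rois_} ROI columns, got {series.shape[1]}"
                )
            cm = pearson_matrix(TimeSeriesSession(subject="", session="pre", data=series))
            if self.use_fisher_z:
                cm = fisher_z(cm)
            out.append(cm.values)
        return np.stack(out)

    @staticmethod
    def _validate(X) -> list[np.ndarray]:
        arrays = [np.asarray(x, dtype=float) for x in X]
        if not arrays:
            raise ValueError("empty input")
        for a in arrays:
            if a.ndim != 2:
                raise ValueError("each sample must be a 2-D (volumes x ROIs) array")
        return arrays


class DensityThreshold(BaseEstimator, TransformerMixin):
    """Binarize connectivity matrices at a fixed connection density.

    Parameters
    ----------
    density : float, default 0.25
        Target edge density in (0, 1].
    ranking : {"signed", "absolute"}, default "signed"
        Edge-weight ranking convention.
    """

    def __init__(self, density: float = 0.25, ranking: str = "signed"):
        self.density = density
        self.ranking = ranking

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("expected a (samples, N, N) stack of square matrices")
        self.n_rois_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_rois_")
        X = np.asarray(X, dtype=float)
        out = []
        for m in X:
            g = threshold_to_density(
                ConnectivityMatrix(values=m), self.density, ranking=self.ranking
            )
            out.append(g.adjacency)
        return np.stack(out)


class GraphMetricsExtractor(BaseEstimator, TransformerMixin):
    """Flatten binary adjacency stacks into per-node graph-index features.

    Output column order is node-major: for each ROI, the six indexes of
    :data:`fcgraph.metrics.NODAL_METRICS`.
    """

    def __init__(self, normalized_betweenness: bool = False):
        self.normalized_betweenness = normalized_betweenness

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("expected a (samples, N, N) stack of adjacency matrices")
        self.n_rois_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_rois_")
        X = np.asarray(X)
        rows = []
        for adj in X:
            table = nodal_metric_table(
                BinaryGraph(adjacency=adj),
                normalized_betweenness=self.normalized_betweenness,
            )
            rows.append(table.to_numpy().ravel())
        return np.stack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "n_rois_")
        return np.asarray(
            [f"node{i}__{m}" for i in range(self.n_rois_) for m in NODAL_METRICS],
            dtype=object,
        )
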