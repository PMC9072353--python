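"""Oocyte expression-matrix plumbing: log2 RPM, variable genes, clustering.

The single-cell RNA analysis quantifies genes as log2-transformed reads per
million, selects highly variable genes as those whose standard deviation
exceeds an intensity-matched trend by more than a threshold (default 0.528
on the log2 scale), and groups the selected genes by agglomerative
hierarchical clustering (Euclidean distance, complete linkage by default).

Matrices are genes x cells throughout (a gene is the unit of selection and
clustering); pandas DataFrames keep gene/cell names attached, plain arrays
are accepted everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = [
    "log2_rpm",
    "select_variable_genes",
    "cluster_genes",
    "pca_cells",
    "VariableGeneSelector",
    "GeneClusterer",
]


def log2_rpm(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """log2(RPM + 1) normalisation of a genes x cells count matrix.

    RPM = count / library total x 10^6 per cell (column).  The +1
    pseudocount keeps zeros at 0 and every value finite.  A cell with a zero
    library total is an error.
    """
    values = np.asarray(counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every cell must have a positive library total")
    out = np.log2(values / totals * 1e6 + 1.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def _running_median_trend(mean: np.ndarray, sd: np.ndarray, window: int) -> np.ndarray:
    """Expected SD at each gene's mean: running median of SD along the mean order."""
    order = np.argsort(mean, kind="mergesort")
    trend_sorted = (
        pd.Series(sd[order]).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    trend = np.empty_like(trend_sorted)
    trend[order] = trend_sorted
    return trend


class VariableGeneSelector(BaseEstimator):
    """Select genes whose SD exceeds the intensity-matched SD trend.

    For each gene the observed standard deviation across cells is compared
    with the expected SD at its mean expression, estimated as a running
    median over genes ordered by mean; a gene is selected when the excess
    (observed - expected) is strictly greater than ``threshold``.

    Parameters
    ----------
    threshold : float, default 0.528
        Selection cut on the SD excess (log2-expression units).
    window : int, default 51
        Width (genes) of the running-median trend.

    Attributes
    ----------
    mean_, sd_, trend_, excess_ : ndarray, per gene
    selected_ : boolean ndarray
    n_selected_ : int
    gene_names_ : Index or None
    """

    def __init__(self, threshold: float = 0.528, window: int = 51) -> None:
        self.threshold = threshold
        self.window = window

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "VariableGeneSelector":
        values = np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[0] < 10:
            raise ValueError("need a genes x cells matrix with at least 10 genes")
        self.gene_names_ = X.index if isinstance(X, pd.DataFrame) else None
        self.mean_ = values.mean(axis=1)
        self.sd_ = values.std(axis=1, ddof=1)
        self.trend_ = _running_median_trend(self.mean_, self.sd_, self.window)
        self.excess_ = self.sd_ - self.trend_
        self.selected_ = self.excess_ > self.threshold
        self.n_selected_ = int(self.selected_.sum())
        return self

    def transform(self, X: pd.DataFrame | np.ndarray):
        """Restrict a genes x cells matrix to the selected genes."""
        if isinstance(X, pd.DataFrame):
            return X.loc[self.selected_]
        return np.asarray(X)[self.selected_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def to_frame(self) -> pd.DataFrame:
        """Per-gene selection table (mean, SD, trend, excess, selected)."""
        frame = pd.DataFrame(
            {
                "mean": self.mean_,
                "sd": self.sd_,
                "trend_sd": self.trend_,
                "excess": self.excess_,
                "selected": self.selected_,
            }
        )
        if self.gene_names_ is not None:
            frame.index = self.gene_names_
        return frame


class GeneClusterer(BaseEstimator):
    """Agglomerative clustering of gene expression profiles.

    Genes (rows) are clustered on their expression vectors with the given
    linkage and metric and the dendrogram is cut into ``n_clusters`` groups.

    Attributes
    ----------
    labels_ : ndarray of cluster ids in 1..n_clusters, one per gene
    linkage_ : the scipy linkage matrix
    cluster_sizes_ : pandas.Series
    """

    def __init__(
        self, n_clusters: int = 5, method: str = "complete", metric: str = "euclidean"
    ) -> None:
        self.n_clusters = n_clusters
        self.method = method
        self.metric = metric

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "GeneClusterer":
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValueError("need a genes x cells matrix")
        n = values.shape[0]
        if self.n_clusters < 1 or self.n_clusters > n:
            raise ValueError(f"n_clusters must lie in [1, {n}]")
        if n == 1:
            self.linkage_ = None
            self.labels_ = np.ones(1, dtype=int)
        else:
            self.linkage_ = hierarchy.linkage(
                pdist(values, metric=self.metric), method=self.method
            )
            self.labels_ = hierarchy.fcluster(
                self.linkage_, t=self.n_clusters, criterion="maxclust"
            )
        self.gene_names_ = X.index if isinstance(X, pd.DataFrame) else None
        self.cluster_sizes_ = pd.Series(self.labels_).value_counts().sort_index()
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def select_variable_genes(
    matrix: pd.DataFrame | np.ndarray, threshold: float = 0.528, window: int = 51
) -> pd.DataFrame:
    """Functional wrapper over :class:`VariableGeneSelector`; returns its table."""
    return VariableGeneSelector(threshold=threshold, window=window).fit(matrix).to_frame()


def cluster_genes(
    matrix: pd.DataFrame | np.ndarray,
    n_clusters: int = 5,
    method: str = "complete",
    metric: str = "euclidean",
) -> np.ndarray:
    """Functional wrapper over :class:`GeneClusterer`; returns the labels."""
    return GeneClusterer(n_clusters=n_clusters, method=method, metric=metric).fit_predict(matrix)


def pca_cells(matrix: pd.DataFrame | np.ndarray, n_components: int = 2) -> pd.DataFrame:
    """PCA of cells (columns) on a genes x cells expression matrix. Plumbing only."""
    values = np.asarray(matrix, dtype=float).T
    scores = PCA(n_components=n_components).fit_transform(values)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    index = matrix.columns if isinstance(matrix, pd.DataFrame) else None
    return pd.DataFrame(scores, columns=cols, index=index)
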