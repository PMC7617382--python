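"""Reduce a neuron table to N binarized functional-cluster time series.

The pipeline mirrors the coarse-graining used for whole-brain calcium data:

1. spatial k-means on neuron positions -> anatomical ROIs (default 1000 on
   real-scale data), each with the unweighted mean trace of its neurons;
2. agglomerative clustering of ROIs on 1 - Pearson correlation of their
   average traces (average linkage) -> N functional clusters;
3. per-cluster z-scoring over time and thresholding (strictly above z -> on)
   -> a T x N binary raster in the chosen state convention.

Each step is exposed both as a scikit-learn-style estimator and as a thin
module-level function.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering, KMeans

from .model import PM1, ZO, MomentSet, _check_convention, moments_from_states


@dataclasses.dataclass
class ROISet:
    n_rois: int
    roi_of_neuron: np.ndarray
    roi_centroids: np.ndarray  # (n_rois, 3)
    roi_traces: np.ndarray  # (n_rois, T)


@dataclasses.dataclass
class ClusterSet:
    n_clusters: int
    cluster_of_roi: np.ndarray
    cluster_traces: np.ndarray  # (N, T)
    covariance_used: np.ndarray  # (n_rois, n_rois)


@dataclasses.dataclass
class BinaryRaster:
    states: np.ndarray  # (T, N)
    threshold_z: float
    convention: str


class SpatialParcellation(BaseEstimator):
    """k-means on neuron x/y/z positions (k-means++ init, 10 restarts).

    ``fit(positions)`` stores ``labels_`` and ``centroids_``;
    ``aggregate(traces)`` averages neuron traces (n_neurons x T) per ROI.
    """

    def __init__(self, n_rois: int = 1000, seed: int = 0, n_init: int = 10):
        self.n_rois = n_rois
        self.seed = seed
        self.n_init = n_init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("positions must be an (n_neurons, 3) array")
        if X.shape[0] < self.n_rois:
            raise ValueError(
                f"need at least n_rois={self.n_rois} neurons, got {X.shape[0]}"
            )
        km = KMeans(
            n_clusters=self.n_rois,
            init="k-means++",
            n_init=self.n_init,
            random_state=self.seed,
        ).fit(X)
        self.labels_ = km.labels_
        self.centroids_ = km.cluster_centers_
        self.n_features_in_ = 3
        return self

    def aggregate(self, traces: np.ndarray) -> np.ndarray:
        traces = np.asarray(traces, dtype=float)
        out = np.empty((self.n_rois, traces.shape[1]))
        for r in range(self.n_rois):
            out[r] = traces[self.labels_ == r].mean(axis=0)
        return out


def spatial_kmeans(positions, traces, n_rois: int, seed: int = 0) -> ROISet:
    """Cluster neurons spatially and average their traces per ROI."""
    est = SpatialParcellation(n_rois=n_rois, seed=seed).fit(positions)
    # centroids as means of member positions (k-means centers equal these at
    # convergence; recompute to satisfy the invariant exactly)
    positions = np.asarray(positions, dtype=float)
    centroids = np.vstack(
        [positions[est.labels_ == r].mean(axis=0) for r in range(n_rois)]
    )
    return ROISet(n_rois, est.labels_, centroids, est.aggregate(traces))


class FunctionalParcellation(BaseEstimator):
    """Agglomerative clustering of ROI traces on 1 - Pearson correlation.

    Average linkage by default; correlation distance makes the partition
    invariant to per-ROI trace scaling.
    """

    def __init__(self, n_clusters: int = 12, linkage: str = "average"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X, y=None):
        """X: (n_rois, T) ROI-average traces."""
        X = np.asarray(X, dtype=float)
        n_rois = X.shape[0]
        if not 2 <= self.n_clusters <= n_rois:
            raise ValueError("need 2 <= n_clusters <= n_rois")
        sd = X.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"ROI(s) {bad.tolist()} have constant traces (zero variance)")
        corr = np.corrcoef(X)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        agg = AgglomerativeClustering(
            n_clusters=self.n_clusters, metric="precomputed", linkage=self.linkage
        ).fit(dist)
        self.labels_ = agg.labels_
        self.covariance_ = np.cov(X)
        self.n_features_in_ = X.shape[1]
        return self

    def aggregate(self, roi_traces: np.ndarray) -> np.ndarray:
        roi_traces = np.asarray(roi_traces, dtype=float)
        out = np.empty((self.n_clusters, roi_traces.shape[1]))
        for c in range(self.n_clusters):
            out[c] = roi_traces[self.labels_ == c].mean(axis=0)
        return out


def functional_clusters(rois: ROISet, n_clusters: int, linkage: str = "average") -> ClusterSet:
    est = FunctionalParcellation(n_clusters=n_clusters, linkage=linkage).fit(rois.roi_traces)
    return ClusterSet(n_clusters, est.labels_, est.aggregate(rois.roi_traces), est.covariance_)


class ZScoreBinarizer(BaseEstimator):
    """Per-feature z-score over time, then strict threshold (> z -> on).

    Operates on a (T, N) trace array (samples x clusters).  ``transform``
    returns the raster in the requested convention (+-1 or 0/1).
    """

    def __init__(self, threshold_z: float = 0.0, convention: str = PM1):
        self.threshold_z = threshold_z
        self.convention = convention

    def fit(self, X, y=None):
        _check_convention(self.convention)
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        bad = np.flatnonzero(self.scale_ == 0)
        if bad.size:
            raise ValueError(f"cluster(s) {bad.tolist()} have zero variance; cannot z-score")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        on = z > self.threshold_z
        off = -1.0 if self.convention == PM1 else 0.0
        return np.where(on, 1.0, off)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def binarize(clusters, threshold_z: float = 0.0, convention: str = PM1) -> BinaryRaster:
    """Binarize cluster traces ((N, T) in a ClusterSet, or raw array) at z."""
    traces = clusters.cluster_traces if isinstance(clusters, ClusterSet) else np.asarray(clusters)
    states = ZScoreBinarizer(threshold_z, convention).fit_transform(traces.T)
    return BinaryRaster(states=states, threshold_z=threshold_z, convention=convention)


def empirical_moments(raster: BinaryRaster | np.ndarray, convention: str = PM1) -> MomentSet:
    """Means and second moments (diagonal included) of a binary raster."""
    if isinstance(raster, BinaryRaster):
        return moments_from_states(raster.states, raster.convention)
    return moments_from_states(raster, convention)


def concatenate_rasters(rasters: list[BinaryRaster]) -> BinaryRaster:
    """Time-axis concatenation of rasters sharing a cluster definition.

    Per-cluster z-scoring is done per recording before this step; no further
    cross-recording normalization is applied.
    """
    if not rasters:
        raise ValueError("no rasters to concatenate")
    conv = rasters[0].convention
    thr = rasters[0].threshold_z
    if any(r.convention != conv or r.states.shape[1] != rasters[0].states.shape[1] for r in rasters):
        raise ValueError("rasters must share convention and cluster count")
    return BinaryRaster(np.vstack([r.states for r in rasters]), thr, conv)
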