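"""Pixel-domain and mass-domain clustering of embedded coordinates.

Pixel domain: Ward agglomerative clustering on a seeded uniform subsample,
followed by nearest-centroid assignment of every pixel, with the cluster
number either fixed or chosen in [2, 8] by maximum mean silhouette.  Every
pixel receives a label — the segmentation map has full coverage.

Mass domain: hierarchical density-based clustering (HDBSCAN) of the 2-D
embedded peaks; peaks in no dense region carry the noise label -1 and render
gray, mirroring how unclustered channels are displayed.
"""

from __future__ import annotations

import colorsys
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN
from sklearn.metrics import pairwise_distances, silhouette_score
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "LabelImage",
    "WardPixelClusterer",
    "PeakDensityClusterer",
    "cluster_pixels",
    "cluster_peaks",
    "transpose_matrix",
    "render_labels",
    "make_palette",
]

NOISE = -1
_GRAY = np.array([128, 128, 128], dtype=np.uint8)


def make_palette(n_clusters: int) -> np.ndarray:
    """Deterministic (n, 3) uint8 palette: evenly spaced saturated hues."""
    cols = []
    for i in range(n_clusters):
        h = (i / max(n_clusters, 1)) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.75, 0.95)
        cols.append((round(r * 255), round(g * 255), round(b * 255)))
    return np.array(cols, dtype=np.uint8).reshape(n_clusters, 3)


@dataclass
class LabelImage:
    """Cluster labels over pixels (H x W) or peaks (length K, -1 = noise)."""

    labels: np.ndarray
    n_clusters: int
    domain: Literal["pixel", "peak"]
    palette: np.ndarray = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.domain == "pixel":
            if self.labels.ndim != 2:
                raise ValueError("pixel-domain labels must be an H x W image")
            if self.labels.min(initial=0) < 0:
                raise ValueError("noise label forbidden in the pixel domain")
        elif self.domain == "peak":
            if self.labels.ndim != 1:
                raise ValueError("peak-domain labels must be a 1-D array")
            if self.labels.size and self.labels.min() < NOISE:
                raise ValueError("labels below -1 are invalid")
        else:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.labels.size and self.labels.max(initial=-1) >= self.n_clusters:
            raise ValueError("label exceeds declared n_clusters")
        if self.palette is None:
            self.palette = make_palette(self.n_clusters)


class WardPixelClusterer(ClusterMixin, BaseEstimator):
    """Ward clustering on a subsample + nearest-centroid assignment.

    Parameters
    ----------
    n_clusters : int or "auto"; auto picks k in ``k_range`` by maximum mean
        silhouette on the subsample.
    max_sample : subsample size for the Ward dendrogram (full pairwise Ward on
        tens of millions of pixels is infeasible; the subsample seed makes the
        result reproducible).
    random_state : subsample seed.

    Fitted attributes: ``centroids_``, ``n_clusters_``, ``labels_``,
    ``silhouette_by_k_`` (auto mode).
    """

    def __init__(self, n_clusters: int | str = "auto", k_range: tuple[int, int] = (2, 8),
                 max_sample: int = 8000, random_state: int = 0):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.max_sample = max_sample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        n = X.shape[0]
        if isinstance(self.n_clusters, (int, np.integer)) and self.n_clusters > n:
            raise ValueError(f"k_clusters={self.n_clusters} exceeds {n} points")
        rng = np.random.default_rng(self.random_state)
        if n > self.max_sample:
            sub_idx = rng.choice(n, size=self.max_sample, replace=False)
            sub_idx.sort()
        else:
            sub_idx = np.arange(n)
        sub = X[sub_idx]

        if self.n_clusters == "auto":
            k = self._select_k(sub)
        else:
            k = int(self.n_clusters)
        if k == 1:
            sub_labels = np.zeros(sub.shape[0], dtype=np.int64)
        else:
            Z = linkage(sub, method="ward")
            sub_labels = fcluster(Z, t=k, criterion="maxclust") - 1
        self.centroids_ = np.vstack(
            [sub[sub_labels == c].mean(axis=0) for c in range(int(sub_labels.max()) + 1)]
        )
        labels = self._assign(X)
        # canonicalize: renumber clusters by first occurrence in row-major order
        labels, self.centroids_ = _canonicalize(labels, self.centroids_)
        self.labels_ = labels
        self.n_clusters_ = self.centroids_.shape[0]
        return self

    def _select_k(self, sub: np.ndarray) -> int:
        lo, hi = self.k_range
        hi = min(hi, sub.shape[0] - 1)
        Z = linkage(sub, method="ward")
        D = pairwise_distances(sub).astype(np.float64)
        scores: dict[int, float] = {}
        for k in range(lo, hi + 1):
            lab = fcluster(Z, t=k, criterion="maxclust") - 1
            if np.unique(lab).size < 2:
                continue
            scores[k] = float(silhouette_score(D, lab, metric="precomputed"))
        self.silhouette_by_k_ = scores
        if not scores:
            return 1
        return max(scores, key=scores.get)

    def _assign(self, X: np.ndarray) -> np.ndarray:
        labels = np.empty(X.shape[0], dtype=np.int64)
        block = 1 << 18
        for start in range(0, X.shape[0], block):
            xb = X[start : start + block]
            d2 = ((xb[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
            labels[start : start + block] = d2.argmin(axis=1)
        return labels

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        X = check_array(X, dtype=np.float64)
        raw = self._assign(X)
        return raw

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _canonicalize(labels: np.ndarray, centroids: np.ndarray):
    """Renumber labels by order of first appearance; drop empty clusters."""
    uniq, first = np.unique(labels, return_index=True)
    order = uniq[np.argsort(first)]
    remap = np.empty(int(labels.max()) + 1, dtype=np.int64)
    remap[order] = np.arange(order.size)
    return remap[labels], centroids[order]


class PeakDensityClusterer(ClusterMixin, BaseEstimator):
    """Density-based hierarchical clustering of embedded peaks (HDBSCAN).

    Peaks that fall in no dense region get the noise label -1.  All points
    identical is treated as a single dense cluster; ``min_cluster_size``
    larger than the number of points forces everything to noise.
    """

    def __init__(self, min_cluster_size: int = 5):
        self.min_cluster_size = min_cluster_size

    def fit_predict(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        n = X.shape[0]
        if self.min_cluster_size > n:
            warnings.warn(
                f"min_cluster_size {self.min_cluster_size} > {n} points: all noise"
            )
            self.labels_ = np.full(n, NOISE, dtype=np.int64)
            self.n_clusters_ = 0
            return self.labels_
        if np.allclose(X, X[0]):
            self.labels_ = np.zeros(n, dtype=np.int64)
            self.n_clusters_ = 1
            return self.labels_
        labels = HDBSCAN(min_cluster_size=int(self.min_cluster_size), copy=True).fit_predict(X)
        self.labels_ = labels.astype(np.int64)
        self.n_clusters_ = int(labels.max()) + 1
        if self.n_clusters_ == 0:
            warnings.warn("no dense region found: every peak labeled noise")
        return self.labels_

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self


def cluster_pixels(coords: np.ndarray, geometry: tuple[int, int],
                   k_clusters: int | str = "auto", seed: int = 0,
                   max_sample: int = 8000) -> LabelImage:
    """Cluster backfitted pixel coordinates into a full-coverage label image."""
    coords = np.asarray(coords)
    H, W = geometry
    if coords.shape[0] != H * W:
        raise ValueError(f"{coords.shape[0]} coordinates cannot fill {H}x{W}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    est = WardPixelClusterer(n_clusters=k_clusters, max_sample=max_sample,
                             random_state=seed)
    labels = est.fit_predict(coords)
    return LabelImage(labels.reshape(H, W), est.n_clusters_, "pixel")


def cluster_peaks(coords: np.ndarray, min_cluster_size: int = 5) -> LabelImage:
    """Cluster embedded peaks; unclustered peaks get the noise label -1."""
    est = PeakDensityClusterer(min_cluster_size=min_cluster_size)
    labels = est.fit_predict(np.asarray(coords))
    return LabelImage(labels, est.n_clusters_, "peak")


def transpose_matrix(X: np.ndarray) -> np.ndarray:
    """Swap the spatial and mass domains: (N, K) -> (K, N), peaks as rows."""
    return np.ascontiguousarray(np.asarray(X).T)


def render_labels(label_image: LabelImage) -> np.ndarray:
    """False-color uint8 RGB rendering; noise (peak domain) renders gray.

    Peak-domain labels render as a 1-pixel-tall strip (K x 1 x 3 transposed to
    1 x K x 3) so the same function serves both domains.
    """
    labels = label_image.labels
    if label_image.domain == "peak":
        labels = labels.reshape(1, -1)
    out = np.empty(labels.shape + (3,), dtype=np.uint8)
    noise = labels == NOISE
    out[noise] = _GRAY
    valid = ~noise
    if label_image.n_clusters > 0:
        out[valid] = label_image.palette[labels[valid]]
    return out
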