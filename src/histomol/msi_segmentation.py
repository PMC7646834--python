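"""Spatially-aware segmentation of MSI data by shrunken centroids.

The algorithm combines nearest-shrunken-centroid statistics with spatial
smoothing of the per-pixel discriminant scores: starting from a seeded
k-means partition, each iteration (1) computes cluster feature means, the
pooled within-cluster SD per feature s_j and its median s0, (2) forms the
standardized centroid contrasts d_kj = (xbar_kj - xbar_j) / (m_k (s_j + s0))
with m_k = sqrt(1/n_k - 1/n), soft-thresholds them by the shrinkage
parameter s, and rebuilds shrunken centroids from the surviving contrasts,
(3) reassigns every pixel to the cluster minimizing its spatially smoothed
standardized distance to the shrunken centroid, where the smoothing
averages scores over a Chebyshev neighborhood of radius r with Gaussian
distance weights, optionally multiplied by adaptive (feature-similarity)
weights.  Empty clusters are dropped; iteration stops at label convergence.

With r = 0 and s = 0 the procedure reduces to standardized k-means from the
same initialization; larger s suppresses uninformative features and merges
clusters (all centroids collapse onto the global mean once s exceeds every
|d_kj|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .msi_preprocess import FeatureMatrix

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "SpatialShrunkenCentroids",
    "spatial_shrunken_centroids",
    "select_tumor_clusters",
    "compare_regions",
]


@dataclass
class SegmentationParams:
    """Tuning triple (r, k, s) plus iteration controls."""

    k_init: int = 8
    r: int = 1
    s: float = 0.0
    max_iter: int = 30
    seed: int = 0
    weights: str = "adaptive"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.k_init < 1:
            raise ValueError("k_init must be >= 1")
        if self.r < 0 or self.s < 0:
            raise ValueError("r and s must be >= 0")
        if self.weights not in ("gaussian", "adaptive"):
            raise ValueError("weights must be 'gaussian' or 'adaptive'")


@dataclass
class SegmentationResult:
    """Per-pixel labels plus per-cluster shrunken centroid statistics."""

    labels: np.ndarray  # 1-based contiguous cluster ids
    coordinates: list[tuple[int, int]]
    centroids: np.ndarray  # clusters x features (shrunken)
    tstats: np.ndarray  # clusters x features soft-thresholded statistics
    n_iterations: int
    params: SegmentationParams
    objective_trace: list[float] = field(default_factory=list)
    init_labels: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def pixels_of(self, cluster: int) -> set[tuple[int, int]]:
        return {c for c, l in zip(self.coordinates, self.labels) if l == cluster}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "x": [c[0] for c in self.coordinates],
            "y": [c[1] for c in self.coordinates],
            "cluster": self.labels,
        })

    def save_png(self, path) -> None:
        """Render the cluster label map as an image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        xs = [c[0] for c in self.coordinates]
        ys = [c[1] for c in self.coordinates]
        grid = np.full((max(ys), max(xs)), np.nan)
        for (x, y), l in zip(self.coordinates, self.labels):
            grid[y - 1, x - 1] = l
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(grid, origin="lower", cmap="tab10", interpolation="none")
        fig.colorbar(im, ax=ax, label="cluster")
        ax.set_xlabel("x [pixel]")
        ax.set_ylabel("y [pixel]")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def _neighbor_weights(coords: np.ndarray, X: np.ndarray, r: int, mode: str):
    """Per-pixel neighbor index lists and normalized smoothing weights."""
    n = len(coords)
    if r == 0:
        return [np.array([i]) for i in range(n)], [np.array([1.0]) for _ in range(n)]
    index = {tuple(c): i for i, c in enumerate(coords)}
    neighbors, weights = [], []
    denom = 2.0 * (r / 2.0) ** 2
    for i, (x, y) in enumerate(coords):
        idx, alpha = [], []
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                j = index.get((x + dx, y + dy))
                if j is None:
                    continue
                idx.append(j)
                alpha.append(np.exp(-(dx * dx + dy * dy) / denom))
        idx = np.asarray(idx)
        w = np.asarray(alpha)
        if mode == "adaptive" and len(idx) > 1:
            d2 = np.sum((X[idx] - X[i]) ** 2, axis=1)
            sigma2 = float(np.mean(d2))
            if sigma2 > 0:
                w = w * np.exp(-d2 / (2.0 * sigma2))
        w = w / w.sum()
        neighbors.append(idx)
        weights.append(w)
    return neighbors, weights


class SpatialShrunkenCentroids(ClusterMixin, BaseEstimator):
    """Spatial shrunken centroid clustering as a scikit-learn estimator.

    Parameters
    ----------
    k_init : int
        Maximum number of clusters (k-means++ initialization).
    r : int
        Chebyshev neighborhood radius for spatial smoothing (0 = none).
    s : float
        Soft-threshold shrinkage applied to the standardized centroid
        contrasts; larger s selects fewer features and merges clusters.
    max_iter, seed, weights
        Iteration cap, RNG seed, and spatial weight flavor
        ("gaussian" or "adaptive").

    Attributes
    ----------
    labels_ : 1-based contiguous cluster ids per pixel.
    centroids_ : shrunken centroids (clusters x features).
    tstats_ : soft-thresholded statistics (clusters x features).
    result_ : full :class:`SegmentationResult`.
    """

    def __init__(self, k_init: int = 8, r: int = 1, s: float = 0.0,
                 max_iter: int = 30, seed: int = 0, weights: str = "adaptive"):
        self.k_init = k_init
        self.r = r
        self.s = s
        self.max_iter = max_iter
        self.seed = seed
        self.weights = weights

    def fit(self, X, y=None, coords: Sequence[tuple[int, int]] | None = None):
        params = SegmentationParams(self.k_init, self.r, self.s,
                                    self.max_iter, self.seed, self.weights)
        if isinstance(X, FeatureMatrix):
            if coords is None:
                coords = list(zip(X.row_meta["x"], X.row_meta["y"]))
            X = X.values
        X = np.asarray(X, dtype=np.float64)
        if coords is None:
            raise ValueError("pixel coordinates are required")
        coords_arr = np.asarray(coords, dtype=int)
        n, p = X.shape
        if len(coords_arr) != n:
            raise ValueError("coords must correspond 1-1 to matrix rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if params.k_init > n:
            raise ValueError(f"k_init={params.k_init} exceeds {n} pixels")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # k_init may exceed distinct rows
            km = KMeans(n_clusters=params.k_init, n_init=1,
                        random_state=params.seed)
            labels = km.fit_predict(X)
        init_labels = labels.copy()

        neighbors, nweights = _neighbor_weights(coords_arr, X, params.r, params.weights)
        global_mean = X.mean(axis=0)
        trace: list[float] = []
        centroids = tstats = None
        sd_total = None
        n_iter = 0
        for n_iter in range(1, params.max_iter + 1):
            ids = np.unique(labels)
            K = len(ids)
            means = np.vstack([X[labels == k].mean(axis=0) for k in ids])
            counts = np.array([(labels == k).sum() for k in ids])
            if n > K:
                within = np.zeros(p)
                for k, m in zip(ids, means):
                    within += ((X[labels == k] - m) ** 2).sum(axis=0)
                s_j = np.sqrt(within / (n - K))
            else:
                s_j = np.zeros(p)
            s0 = float(np.median(s_j))
            sd_total = s_j + s0
            if np.all(sd_total == 0):
                sd_total = np.ones(p)
            m_k = np.sqrt(np.maximum(1.0 / counts - 1.0 / n, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                d = (means - global_mean) / (m_k[:, None] * sd_total[None, :])
            d[~np.isfinite(d)] = 0.0
            tstats = np.sign(d) * np.maximum(np.abs(d) - params.s, 0.0)
            centroids = global_mean + m_k[:, None] * sd_total[None, :] * tstats

            Z = X / sd_total
            C = centroids / sd_total
            score = (
                np.sum(Z * Z, axis=1)[:, None]
                - 2.0 * Z @ C.T
                + np.sum(C * C, axis=1)[None, :]
            )
            if params.r > 0:
                smoothed = np.empty_like(score)
                for i in range(n):
                    smoothed[i] = nweights[i] @ score[neighbors[i]]
            else:
                smoothed = score
            new_idx = np.argmin(smoothed, axis=1)
            new_labels = ids[new_idx]
            trace.append(float(smoothed[np.arange(n), new_idx].sum()))
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels

        # contiguous 1-based ids, ordered by first appearance
        ids = np.unique(labels)
        remap = {k: i + 1 for i, k in enumerate(ids)}
        final = np.array([remap[k] for k in labels])
        keep = [np.flatnonzero(np.unique(labels) == k)[0] for k in ids]
        self.labels_ = final
        self.centroids_ = centroids[keep]
        self.tstats_ = tstats[keep]
        self.feature_sd_ = sd_total
        self.result_ = SegmentationResult(
            labels=final,
            coordinates=[tuple(c) for c in coords_arr],
            centroids=self.centroids_,
            tstats=self.tstats_,
            n_iterations=n_iter,
            params=params,
            objective_trace=trace,
            init_labels=init_labels,
        )
        return self

    def fit_predict(self, X, y=None, coords=None):
        return self.fit(X, coords=coords).labels_


def spatial_shrunken_centroids(matrix: FeatureMatrix | np.ndarray,
                               coords: Sequence[tuple[int, int]] | None = None,
                               params: SegmentationParams | None = None,
                               **kwargs) -> SegmentationResult:
    """Functional wrapper around :class:`SpatialShrunkenCentroids`."""
    if params is None:
        params = SegmentationParams(**kwargs)
    est = SpatialShrunkenCentroids(params.k_init, params.r, params.s,
                                   params.max_iter, params.seed, params.weights)
    est.fit(matrix, coords=coords)
    return est.result_


def select_tumor_clusters(segmentation: SegmentationResult,
                          reference_mask: Iterable[tuple[int, int]],
                          threshold: float = 0.5,
                          criterion: str = "jaccard") -> set[tuple[int, int]]:
    """Union of pixels of clusters overlapping the reference annotation.

    ``reference_mask`` stands in for the pathologist's tumor annotation.
    ``criterion`` is "jaccard" (|A&B| / |A|B|union) or "containment"
    (fraction of the cluster's pixels inside the mask — robust when the
    tumor splits into several clusters); a cluster is selected when its
    overlap statistic >= ``threshold``.
    """
    mask = set(reference_mask)
    if not mask:
        raise ValueError("empty reference mask")
    pixels = set(segmentation.coordinates)
    if not mask <= pixels:
        raise ValueError("reference mask contains coordinates outside the dataset")
    selected: set[tuple[int, int]] = set()
    for k in range(1, segmentation.n_clusters + 1):
        cluster = segmentation.pixels_of(k)
        inter = len(cluster & mask)
        if inter == 0:
            continue
        if criterion == "jaccard":
            stat = inter / len(cluster | mask)
        elif criterion == "containment":
            stat = inter / len(cluster)
        else:
            raise ValueError("criterion must be 'jaccard' or 'containment'")
        if stat >= threshold:
            selected |= cluster
    return selected


def compare_regions(cluster_a_pixels: Iterable[tuple[int, int]],
                    cluster_b_pixels: Iterable[tuple[int, int]],
                    spot_assignments: Mapping[str, Iterable[tuple[int, int]]],
                    ) -> dict[str, list[str]]:
    """Group extraction spots by the MSI cluster that contains them.

    ``spot_assignments`` maps each extraction-spot id to the pixel(s) it
    covers.  A spot overlapping both clusters is an error; a spot outside
    both is excluded with a warning; either group ending up empty is an
    error.  The result feeds the two-group volcano contrast.
    """
    a = set(cluster_a_pixels)
    b = set(cluster_b_pixels)
    if a & b:
        raise ValueError("cluster pixel sets overlap")
    groups: dict[str, list[str]] = {"A": [], "B": []}
    for spot, px in spot_assignments.items():
        px = set(px)
        in_a, in_b = bool(px & a), bool(px & b)
        if in_a and in_b:
            raise ValueError(f"extraction spot {spot!r} overlaps both clusters")
        if in_a:
            groups["A"].append(spot)
        elif in_b:
            groups["B"].append(spot)
        else:
            warnings.warn(f"extraction spot {spot!r} lies outside both clusters")
    if not groups["A"] or not groups["B"]:
        raise ValueError("each cluster needs at least one extraction spot")
    return groups
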