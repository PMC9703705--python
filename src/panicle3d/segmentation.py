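"""Panicle segmentation: per-point VARI, connected components, cluster selection.

The reconstructed scene contains the panicle plus clutter (pot rim, labels,
residual chamber points).  Each point gets a greenness score, the Visible
Atmospherically Resistant Index

    VARI = (G - R) / (G + R - B),

computed from its RGB intensities.  The scene is partitioned into spatially
connected components on a voxel grid (26-connectivity), and the component
containing the most points with VARI above a threshold (default 0.1, strict
inequality) is taken as the panicle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

from .cloud import ColoredPointCloud

__all__ = [
    "VariScores",
    "ClusterLabels",
    "compute_vari",
    "cluster_points",
    "select_panicle_cluster",
    "filter_residual_points",
    "default_voxel_size",
    "PanicleSegmenter",
    "NoPanicleError",
]


class NoPanicleError(RuntimeError):
    """Raised when no cluster contains any point above the VARI threshold."""


@dataclass
class VariScores:
    """Per-point VARI values; degenerate denominators carry 0 and a flag."""

    values: np.ndarray
    undefined_flags: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClusterLabels:
    """Connected-component labels 0..n_clusters-1, every cluster non-empty."""

    labels: np.ndarray
    n_clusters: int

    def __len__(self) -> int:
        return len(self.labels)


def compute_vari(cloud: ColoredPointCloud) -> VariScores:
    """Compute VARI = (G-R)/(G+R-B) per point.

    Points with G + R - B = 0 are colorimetrically degenerate; they get the
    sentinel value 0 (which fails any positive greenness threshold) and are
    flagged.
    """
    r, g, b = cloud.colors[:, 0], cloud.colors[:, 1], cloud.colors[:, 2]
    denom = g + r - b
    undefined = denom == 0
    values = np.zeros(cloud.point_count, dtype=np.float64)
    ok = ~undefined
    values[ok] = (g[ok] - r[ok]) / denom[ok]
    return VariScores(values, undefined)


def default_voxel_size(cloud: ColoredPointCloud, factor: float = 2.0) -> float:
    """Heuristic grid resolution: ``factor`` × median nearest-neighbor spacing."""
    n = cloud.point_count
    if n < 2:
        return 1.0
    # subsample for speed on large clouds; spacing statistics are stable
    coords = cloud.coords
    if n > 20000:
        step = n // 20000 + 1
        sample = coords[::step]
    else:
        sample = coords
    tree = cKDTree(coords)
    dist, _ = tree.query(sample, k=2)
    med = float(np.median(dist[:, 1]))
    return factor * med if med > 0 else 1.0


def cluster_points(cloud: ColoredPointCloud, voxel_size: float) -> ClusterLabels:
    """Label spatially connected components on a voxel grid.

    Points sharing a voxel, or whose voxels are 26-adjacent, receive the same
    label.  The partition is exhaustive and disjoint; labels are contiguous
    integers ordered by first occurrence.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    coords = cloud.coords
    keys = np.floor((coords - coords.min(axis=0)) / voxel_size).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    k = len(uniq)
    voxel_index = {tuple(v): i for i, v in enumerate(uniq)}

    rows, cols = [], []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for i, v in enumerate(uniq):
        vx, vy, vz = int(v[0]), int(v[1]), int(v[2])
        for dx, dy, dz in offsets:
            j = voxel_index.get((vx + dx, vy + dy, vz + dz))
            if j is not None and j > i:
                rows.append(i)
                cols.append(j)
    graph = coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(k, k)
    )
    n_comp, voxel_labels = _cc(graph, directed=False)

    point_labels = voxel_labels[inverse]
    # relabel by first occurrence so labels are deterministic in point order
    uniq_labs, first_idx = np.unique(point_labels, return_index=True)
    remap = np.empty(n_comp, dtype=np.int64)
    remap[uniq_labs[np.argsort(first_idx)]] = np.arange(len(uniq_labs))
    return ClusterLabels(remap[point_labels], n_comp)


def select_panicle_cluster(
    cloud: ColoredPointCloud,
    labels: ClusterLabels,
    vari: VariScores,
    vari_threshold: float = 0.1,
) -> ColoredPointCloud:
    """Return the cluster with the most points whose VARI exceeds the threshold.

    The inequality is strict (VARI > threshold).  Ties are broken by larger
    total cluster size, then by lowest label.

    Raises
    ------
    NoPanicleError
        If no cluster has any qualifying point.
    """
    if len(labels) != cloud.point_count or len(vari) != cloud.point_count:
        raise ValueError("labels and vari must align with the cloud")
    qualifying = vari.values > vari_threshold
    q_counts = np.bincount(labels.labels, weights=qualifying, minlength=labels.n_clusters)
    sizes = np.bincount(labels.labels, minlength=labels.n_clusters)
    if q_counts.max() == 0:
        raise NoPanicleError(
            f"no cluster contains a point with VARI > {vari_threshold}"
        )
    # lexicographic: qualifying count, then size, then lowest label
    order = np.lexsort((np.arange(labels.n_clusters), -sizes, -q_counts))
    best = order[0]
    return cloud.subset(labels.labels == best)


def filter_residual_points(
    cloud: ColoredPointCloud,
    vari: VariScores | None = None,
    vari_threshold: float = 0.1,
    mad_factor: float = 5.0,
) -> ColoredPointCloud:
    """Optionally drop residual non-panicle points inside the selected cluster.

    A point is removed when it is both non-green (VARI <= threshold) and a
    spatial outlier (distance from the cluster medoid greater than
    ``mad_factor`` × MAD of all medoid distances) — the signature of a plant
    label or tie riding along in the panicle component.  Off by default in the
    pipeline.
    """
    if vari is None:
        vari = compute_vari(cloud)
    center = np.median(cloud.coords, axis=0)
    d = np.linalg.norm(cloud.coords - center, axis=1)
    mad = np.median(np.abs(d - np.median(d)))
    if mad == 0:
        return cloud
    drop = (vari.values <= vari_threshold) & (d > np.median(d) + mad_factor * mad)
    if drop.all():
        return cloud
    return cloud.subset(~drop)


class PanicleSegmenter(ClusterMixin, BaseEstimator):
    """Cluster a scene point cloud and select the panicle component.

    Follows the scikit-learn clusterer protocol: ``fit`` takes an (N, 6)
    xyzrgb array (or a :class:`ColoredPointCloud`), computes connected
    components on a voxel grid, scores points by VARI, and exposes the
    selected panicle as a boolean mask.

    Parameters
    ----------
    voxel_size : float or None
        Grid resolution for connectivity; ``None`` uses 2× the median
        nearest-neighbor spacing.
    vari_threshold : float
        Greenness cut for the majority rule (strict inequality), default 0.1.
    residual_filter : bool
        Apply the post-selection color/distance outlier filter, default off.

    Attributes
    ----------
    labels_ : (N,) int array
        Connected-component label per point.
    vari_ : (N,) float array
        Per-point VARI scores.
    panicle_label_ : int
        Label of the selected panicle cluster.
    panicle_mask_ : (N,) bool array
        True for points belonging to the selected panicle.
    n_clusters_ : int
        Number of connected components found.
    """

    def __init__(
        self,
        voxel_size: float | None = None,
        vari_threshold: float = 0.1,
        residual_filter: bool = False,
    ):
        self.voxel_size = voxel_size
        self.vari_threshold = vari_threshold
        self.residual_filter = residual_filter

    def _as_cloud(self, X) -> ColoredPointCloud:
        if isinstance(X, ColoredPointCloud):
            return X
        return ColoredPointCloud.from_array(np.asarray(X, dtype=np.float64))

    def fit(self, X, y=None) -> "PanicleSegmenter":
        cloud = self._as_cloud(X)
        vsize = self.voxel_size
        if vsize is None:
            vsize = default_voxel_size(cloud)
        labels = cluster_points(cloud, vsize)
        vari = compute_vari(cloud)
        panicle = select_panicle_cluster(cloud, labels, vari, self.vari_threshold)

        self.voxel_size_ = vsize
        self.labels_ = labels.labels
        self.n_clusters_ = labels.n_clusters
        self.vari_ = vari.values
        qualifying = vari.values > self.vari_threshold
        q_counts = np.bincount(labels.labels, weights=qualifying, minlength=labels.n_clusters)
        sizes = np.bincount(labels.labels, minlength=labels.n_clusters)
        order = np.lexsort((np.arange(labels.n_clusters), -sizes, -q_counts))
        self.panicle_label_ = int(order[0])
        mask = labels.labels == self.panicle_label_
        if self.residual_filter:
            sub = cloud.subset(mask)
            kept = filter_residual_points(sub, vari_threshold=self.vari_threshold)
            # map the kept subset back onto the full-cloud mask
            if kept.point_count < sub.point_count:
                sub_idx = np.flatnonzero(mask)
                keep_local = np.zeros(sub.point_count, dtype=bool)
                # identify kept rows by coordinates (subset preserves order)
                ptr = 0
                for i in range(sub.point_count):
                    if ptr < kept.point_count and np.array_equal(
                        sub.coords[i], kept.coords[ptr]
                    ):
                        keep_local[i] = True
                        ptr += 1
                mask = np.zeros_like(mask)
                mask[sub_idx[keep_local]] = True
        self.panicle_mask_ = mask
        self._cloud = cloud
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the connected-component labels."""
        return self.fit(X).labels_

    def extract(self) -> ColoredPointCloud:
        """Return the segmented panicle sub-cloud (requires a prior fit)."""
        if not hasattr(self, "panicle_mask_"):
            raise RuntimeError("PanicleSegmenter must be fitted before extract()")
        return self._cloud.subset(self.panicle_mask_)

    def cluster_report(self):
        """Per-cluster summary: label, size, qualifying-point count."""
        import pandas as pd

        qualifying = self.vari_ > self.vari_threshold
        rows = []
        for lab in range(self.n_clusters_):
            m = self.labels_ == lab
            rows.append(
                {
                    "label": lab,
                    "size": int(m.sum()),
                    "qualifying_points": int(qualifying[m].sum()),
                    "is_panicle": lab == self.panicle_label_,
                }
            )
        return pd.DataFrame(rows)
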