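"""k-means partitioning of the preprocessed cloud.

The user supplies k larger than the expected component count (1.5-2x is a
good default, see the package docs); over-provisioning prevents single
clusters from spanning several components, and the merging stage later
collapses the surplus. Density-based clustering (DBSCAN) is deliberately
not offered: SfM clouds have strongly inhomogeneous density, which makes
its neighborhood parameters unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import EmptyClusterError
from .io import PointCloud

__all__ = ["ClusterSet", "kmeans_cluster", "extract_cluster"]


@dataclass
class ClusterSet:
    """A partition of a cloud into k clusters (per-point labels in [0, k))."""

    labels: np.ndarray
    k: int
    cloud: PointCloud

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.cloud):
            raise ValueError("labels must cover every point")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def indices_of(self, index: int) -> np.ndarray:
        return np.flatnonzero(self.labels == index)


def kmeans_cluster(cloud: PointCloud, k: int, seed: int = 0) -> ClusterSet:
    """Partition the cloud with Lloyd's algorithm (k-means++ seeding).

    Runs to convergence (centroid motion below 1e-6 or 300 iterations),
    deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(cloud):
        raise ValueError(f"k={k} exceeds point count {len(cloud)}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-6,
        random_state=int(seed) % (2**31),
    )
    labels = km.fit_predict(cloud.positions)
    return ClusterSet(labels, k, cloud)


def extract_cluster(clusters: ClusterSet, index: int) -> PointCloud:
    """Sub-cloud carrying the given label, point order preserved."""
    if not 0 <= index < clusters.k:
        raise IndexError(f"cluster index {index} out of range [0, {clusters.k})")
    idx = clusters.indices_of(index)
    if len(idx) == 0:
        raise EmptyClusterError(f"cluster {index} is empty")
    return clusters.cloud.select(idx)
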