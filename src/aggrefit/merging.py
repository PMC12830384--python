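"""Overlap-driven cluster merging, iterated to a fixpoint.

Over-provisioned k-means typically splits single components across several
clusters; the spheres fitted to those clusters then overlap. Two fitted
spheres overlap when their center distance is strictly below
``alpha * (r_i + r_j)`` with ``alpha = 0.9``. Each merge round pools every
connected group of overlapping fits, re-clusters the pooled points with
k equal to the group size minus one, refits the new clusters, and repeats
until no overlap remains. Since k strictly decreases whenever anything
overlaps, termination within the initial k rounds is guaranteed.

For non-spherical templates the overlap predicate is replaced by the
inside-fraction test from :mod:`aggrefit.nonspherical`.
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional

import numpy as np

from .clustering import ClusterSet, kmeans_cluster
from .fitting import FitResult, RansacConfig, SphereModel, fit_component, sub_seed
from .io import ComponentMesh, PointCloud

__all__ = [
    "spheres_overlap",
    "build_overlap_edges",
    "merge_step",
    "merge_to_fixpoint",
]

OverlapPredicate = Callable[[FitResult, FitResult], bool]


def spheres_overlap(a: SphereModel, b: SphereModel, alpha: float = 0.9) -> bool:
    """Strictly ``||c_a - c_b|| < alpha (r_a + r_b)``."""
    return bool(np.linalg.norm(a.center - b.center) < alpha * (a.radius + b.radius))


def build_overlap_edges(
    fits: list[Optional[FitResult]],
    alpha: float = 0.9,
    predicate: Optional[OverlapPredicate] = None,
) -> list[tuple[int, int]]:
    """Unordered overlap edges between clusters with valid fits."""
    pred = predicate or (lambda fa, fb: spheres_overlap(fa.sphere, fb.sphere, alpha))
    nodes = [i for i, f in enumerate(fits) if f is not None and f.valid]
    edges = []
    for ii, i in enumerate(nodes):
        for j in nodes[ii + 1 :]:
            if pred(fits[i], fits[j]):
                edges.append((i, j))
    return edges


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_step(
    clusters: ClusterSet,
    fits: list[Optional[FitResult]],
    cfg: RansacConfig,
    seed: int = 0,
    alpha: float = 0.9,
    template: Optional[ComponentMesh] = None,
    predicate: Optional[OverlapPredicate] = None,
    round_index: int = 0,
) -> tuple[ClusterSet, list[Optional[FitResult]], bool]:
    """One merge round: pool overlapping groups, re-cluster at m-1, refit.

    Groups are the connected components of the overlap graph. A pair merges
    into a single cluster; a group of m >= 3 is re-clustered by k-means with
    k = m - 1. Untouched clusters keep their fits; clusters without a fit
    are carried through and refit with a fresh sub-seed each round. The
    changed flag is true iff any overlap edge existed.
    """
    if len(fits) != clusters.k:
        raise ValueError("fits must align with clusters")
    edges = build_overlap_edges(fits, alpha, predicate)
    changed = len(edges) > 0
    uf = _UnionFind(clusters.k)
    for i, j in edges:
        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i, j in edges:
        groups.setdefault(uf.find(i), None)
    for root in list(groups):
        groups[root] = [i for i in range(clusters.k) if uf.find(i) == root]
    merged_members = {i for g in groups.values() for i in g}

    n_points = len(clusters.cloud)
    new_labels = np.full(n_points, -1, dtype=np.int64)
    new_fits: list[Optional[FitResult]] = []
    label = 0
    for i in range(clusters.k):
        if i in merged_members:
            continue
        idx = clusters.indices_of(i)
        new_labels[idx] = label
        fit = fits[i]
        if fit is None and len(idx) > 0:
            fit = fit_component(
                clusters.cloud.select(idx),
                cfg,
                seed=sub_seed(seed, 7, round_index, label),
                template=template,
            )
        new_fits.append(fit)
        label += 1
    for root in sorted(groups):
        members = groups[root]
        idx = np.concatenate([clusters.indices_of(i) for i in members])
        idx.sort()
        pooled = clusters.cloud.select(idx)
        m = len(members)
        if m == 2:
            sub_labels = np.zeros(len(idx), dtype=np.int64)
            n_new = 1
        else:
            sub = kmeans_cluster(pooled, m - 1, seed=sub_seed(seed, 8, round_index, root))
            sub_labels = sub.labels
            n_new = m - 1
        for s in range(n_new):
            sel = idx[sub_labels == s]
            new_labels[sel] = label
            fit = None
            if len(sel) > 0:
                fit = fit_component(
                    clusters.cloud.select(sel),
                    cfg,
                    seed=sub_seed(seed, 9, round_index, label),
                    template=template,
                )
            new_fits.append(fit)
            label += 1
    new_clusters = ClusterSet(new_labels, label, clusters.cloud)
    return new_clusters, new_fits, changed


def merge_to_fixpoint(
    clusters: ClusterSet,
    fits: list[Optional[FitResult]],
    cfg: RansacConfig,
    seed: int = 0,
    alpha: float = 0.9,
    max_rounds: Optional[int] = None,
    template: Optional[ComponentMesh] = None,
    predicate: Optional[OverlapPredicate] = None,
) -> tuple[ClusterSet, list[Optional[FitResult]], list[dict]]:
    """Repeat :func:`merge_step` until no overlaps remain (or the round cap).

    Returns the final clusters and fits together with a per-round log of
    cluster counts and merge activity.
    """
    max_rounds = max_rounds if max_rounds is not None else clusters.k
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    log: list[dict] = []
    for round_index in range(max_rounds):
        k_before = clusters.k
        clusters, fits, changed = merge_step(
            clusters,
            fits,
            cfg,
            seed=seed,
            alpha=alpha,
            template=template,
            predicate=predicate,
            round_index=round_index,
        )
        log.append(
            {
                "round": round_index,
                "k_before": k_before,
                "k_after": clusters.k,
                "changed": changed,
            }
        )
        if not changed:
            return clusters, fits, log
    warnings.warn(
        f"merge_to_fixpoint hit the round cap ({max_rounds}) with overlaps remaining",
        RuntimeWarning,
        stacklevel=2,
    )
    return clusters, fits, log
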