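"""RANSAC component fitting: hypothesis generation + chamfer refinement.

This is the core of the pipeline. For each cluster we repeatedly

1. draw a small random subsample (10% of the cluster, at least 3 points),
2. place the template sphere at the subsample centroid with the user's
   initial radius, and refine it by a greedy grid descent that, per
   iteration, scores 35 candidate spheres — 7 translations (none, +/- one
   step along each axis) times 5 radius scalings (0.8, 0.9, 1.0, 1.1, 1.2)
   — by the symmetric chamfer distance between the subsample and the placed
   template-mesh vertices, adopting the best candidate,
3. classify every cluster point as inlier/outlier by its distance to the
   refined sphere surface, ``d_p = | r - ||x_p - c|| |``; a hypothesis is
   valid when the inlier fraction strictly exceeds 50%.

The valid hypothesis with the smallest chamfer distance (recomputed against
its inlier points) wins. Refinement stops when the chamfer falls below
``d_th1``, improves by less than ``d_th2``, or hits the iteration cap.

For non-spherical templates the point-to-sphere inlier test is replaced by
the fraction of template vertices lying within ``epsilon`` of the cluster,
and six rotated candidates (+/- the rotation step about each axis) augment
the grid (see :mod:`aggrefit.nonspherical`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .io import ComponentMesh, PointCloud, placed_vertices
from .nonspherical import rotation_variants, vertex_inlier_fraction

__all__ = [
    "SphereModel",
    "FitResult",
    "RansacConfig",
    "point_to_sphere_distance",
    "sphere_distances",
    "chamfer_distance",
    "refinement_candidates",
    "refine_locally",
    "generate_hypothesis",
    "fit_component",
    "sub_seed",
]

ArrayLike = Union[np.ndarray, PointCloud]


def _positions(x: ArrayLike) -> np.ndarray:
    if isinstance(x, PointCloud):
        return x.positions
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def sub_seed(*parts: int) -> int:
    """Derive a deterministic 31-bit sub-seed from non-negative integer tags."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SphereModel:
    """Hypothesis sphere: center c and radius r."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.radius = float(self.radius)
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("center must be a finite 3-vector")
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError("radius must be positive and finite")


@dataclass
class RansacConfig:
    """All fitting thresholds; defaults are the method's standard values."""

    n_hypo: int = 50
    n_refi: int = 50
    sample_fraction: float = 0.10
    epsilon: float = 0.015
    min_inlier_ratio: float = 0.5
    d_th1: float = 0.015
    d_th2: float = 0.001
    translation_step: float = 0.01
    scale_factors: Sequence[float] = (0.8, 0.9, 1.0, 1.1, 1.2)
    initial_radius: float = 0.1
    template_subdivisions: int = 2
    min_cluster_points: int = 10
    # non-spherical extensions; the vertex-fraction cutoff sits below the
    # (1 - occlusion) / 2 coverage bound so that a correct hypothesis on a
    # component split across two clusters can still validate
    rotate_hypotheses: bool = False
    vertex_inlier: bool = False
    min_vertex_inlier_fraction: float = 0.35
    rotation_step_deg: float = 10.0

    def __post_init__(self) -> None:
        if 1.0 not in tuple(self.scale_factors):
            raise ValueError("scale_factors must contain 1.0")
        for name in (
            "n_hypo",
            "n_refi",
            "sample_fraction",
            "epsilon",
            "d_th1",
            "d_th2",
            "translation_step",
            "initial_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class FitResult:
    """Outcome of fitting one hypothesis (or the best over all hypotheses)."""

    sphere: SphereModel
    chamfer: float
    inlier_ratio: float
    valid: bool
    iterations_used: int
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    n_points: int = 0
    trace: Optional[list] = None

    def __post_init__(self) -> None:
        if self.chamfer < 0:
            raise ValueError("chamfer must be non-negative")
        # the spherical rule requires > 0.5; the generalized vertex criterion
        # may use a lower configurable cutoff, so only positivity is enforced
        if self.valid and not self.inlier_ratio > 0.0:
            raise ValueError("a valid fit requires a positive inlier ratio")


@lru_cache(maxsize=8)
def _default_template(subdivisions: int) -> ComponentMesh:
    return ComponentMesh.unit_sphere(subdivisions)


def point_to_sphere_distance(p: np.ndarray, sphere: SphereModel) -> float:
    """Unsigned distance from a point to the sphere surface, |r - ||p - c|||."""
    return float(abs(sphere.radius - np.linalg.norm(np.asarray(p, dtype=float) - sphere.center)))


def sphere_distances(points: ArrayLike, sphere: SphereModel) -> np.ndarray:
    """Vectorized surface distances for many points."""
    pos = _positions(points)
    return np.abs(sphere.radius - np.linalg.norm(pos - sphere.center, axis=1))


def chamfer_distance(a: ArrayLike, b: ArrayLike) -> float:
    """Symmetric chamfer distance: mean-of-nearest A->B plus mean-of-nearest B->A."""
    pa, pb = _positions(a), _positions(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("chamfer_distance requires two non-empty point sets")
    d = cdist(pa, pb)
    return float(d.min(axis=1).mean() + d.min(axis=0).mean())


def refinement_candidates(cfg: RansacConfig) -> list[tuple[np.ndarray, float]]:
    """The per-iteration candidate grid: (translation offset, scale factor).

    7 translations (identity first, then +/- along x, y, z) crossed with the
    scale factors (1.0 first), giving 35 candidates with the identity at
    index 0 so that ties favor not moving.
    """
    step = cfg.translation_step
    offsets = [np.zeros(3)]
    for axis in range(3):
        for sign in (+1.0, -1.0):
            off = np.zeros(3)
            off[axis] = sign * step
            offsets.append(off)
    scales = [1.0] + [s for s in cfg.scale_factors if s != 1.0]
    return [(off, s) for off in offsets for s in scales]


def _grid_chamfers(
    X: np.ndarray,
    center: np.ndarray,
    radius: float,
    W: np.ndarray,
    offsets: np.ndarray,
    scales: np.ndarray,
) -> np.ndarray:
    """Chamfer of every (offset, scale) candidate, shape (n_off, n_scale).

    W holds the template vertices already rotated into the current pose;
    candidate vertex sets are ``center + off + (radius * s) * W``.
    """
    centers = center + offsets  # (T, 3)
    Y = X[None, :, :] - centers[:, None, :]  # (T, N, 3)
    yy = np.einsum("tnd,tnd->tn", Y, Y)  # (T, N)
    G = Y @ W.T  # (T, N, V)
    vv = np.einsum("vd,vd->v", W, W)  # (V,)
    s = radius * scales  # (S,)
    d2 = (
        yy[:, None, :, None]
        + (s[:, None] ** 2 * vv[None, :])[None, :, None, :]
        - 2.0 * s[None, :, None, None] * G[:, None, :, :]
    )
    d = np.sqrt(np.maximum(d2, 0.0))  # (T, S, N, V)
    return d.min(axis=3).mean(axis=2) + d.min(axis=2).mean(axis=2)


def refine_locally(
    samples: ArrayLike,
    init: SphereModel,
    template: Optional[ComponentMesh] = None,
    cfg: Optional[RansacConfig] = None,
    rotation: Optional[np.ndarray] = None,
) -> FitResult:
    """Greedy grid descent of the chamfer objective from an initial sphere.

    Per iteration every candidate on the translation x scale grid (and, when
    ``cfg.rotate_hypotheses`` is set, six rotated variants of the current
    pose) is scored by the symmetric chamfer distance between the samples
    and the placed template vertices; the best candidate is adopted if it
    strictly improves. The chamfer trace is therefore non-increasing.
    """
    cfg = cfg or RansacConfig()
    template = template or _default_template(cfg.template_subdivisions)
    X = _positions(samples)
    if len(X) == 0:
        raise ValueError("samples must be non-empty")
    cands = refinement_candidates(cfg)
    n_scales = len(tuple(cfg.scale_factors))
    offsets = np.array([cands[i * n_scales][0] for i in range(len(cands) // n_scales)])
    scales = np.array([s for _, s in cands[:n_scales]])

    c = init.center.copy()
    r = float(init.radius)
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=np.float64).copy()
    rot_moves = rotation_variants(cfg.rotation_step_deg)[1:] if cfg.rotate_hypotheses else []

    def placed(Rcur: np.ndarray) -> np.ndarray:
        return template.vertices @ Rcur.T

    W = placed(R)
    best = chamfer_distance(X, c + r * W)
    trace = [best]
    iterations = 0
    for _ in range(cfg.n_refi):
        iterations += 1
        grid = _grid_chamfers(X, c, r, W, offsets, scales)
        flat = grid.ravel()  # enumeration order: offset-major, scale order as above
        j = int(np.argmin(flat))
        cand_val = float(flat[j])
        move = ("grid", j)
        if rot_moves:
            for m, rv in enumerate(rot_moves):
                Wm = placed(rv @ R)
                val = chamfer_distance(X, c + r * Wm)
                if val < cand_val:
                    cand_val = val
                    move = ("rot", m)
        improvement = best - cand_val
        if cand_val < best:
            if move[0] == "grid":
                ti, si = divmod(move[1], len(scales))
                c = c + offsets[ti]
                r = r * float(scales[si])
            else:
                R = rot_moves[move[1]] @ R
                u, _, vt = np.linalg.svd(R)
                R = u @ vt
                W = placed(R)
            best = cand_val
        trace.append(best)
        if best < cfg.d_th1:
            break
        if improvement < cfg.d_th2:
            break
    return FitResult(
        sphere=SphereModel(c, r),
        chamfer=best,
        inlier_ratio=0.0,
        valid=False,
        iterations_used=iterations,
        rotation=R,
        n_points=len(X),
        trace=trace,
    )


def generate_hypothesis(
    cluster: ArrayLike,
    cfg: Optional[RansacConfig] = None,
    seed: Union[int, np.random.Generator] = 0,
    template: Optional[ComponentMesh] = None,
) -> Optional[FitResult]:
    """One RANSAC hypothesis: subsample, refine, then validate on the cluster.

    Returns ``None`` (skip signal) for clusters below the minimum size.
    The returned result's ``chamfer`` is, for valid hypotheses, recomputed
    between the placed template vertices and the inlier points (all cluster
    points when the generalized vertex criterion is active).
    """
    cfg = cfg or RansacConfig()
    template = template or _default_template(cfg.template_subdivisions)
    X = _positions(cluster)
    if len(X) < cfg.min_cluster_points:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        np.random.SeedSequence([int(seed)])
    )
    m = max(3, int(round(cfg.sample_fraction * len(X))))
    m = min(m, len(X))
    sample = X[rng.choice(len(X), size=m, replace=False)]
    init = SphereModel(sample.mean(axis=0), cfg.initial_radius)
    refined = refine_locally(sample, init, template, cfg)
    sphere, R = refined.sphere, refined.rotation
    verts = placed_vertices(template.vertices, sphere.center, sphere.radius, R)
    if cfg.vertex_inlier:
        ratio = vertex_inlier_fraction(verts, X, cfg.epsilon)
        valid = ratio > cfg.min_vertex_inlier_fraction
        chamfer = chamfer_distance(X, verts) if valid else refined.chamfer
    else:
        dists = sphere_distances(X, sphere)
        mask = dists < cfg.epsilon  # strict
        ratio = float(mask.mean())
        valid = ratio > cfg.min_inlier_ratio  # strict
        chamfer = chamfer_distance(X[mask], verts) if valid else refined.chamfer
    return FitResult(
        sphere=sphere,
        chamfer=chamfer,
        inlier_ratio=ratio,
        valid=valid,
        iterations_used=refined.iterations_used,
        rotation=R,
        n_points=len(X),
    )


def fit_component(
    cluster: ArrayLike,
    cfg: Optional[RansacConfig] = None,
    seed: int = 0,
    template: Optional[ComponentMesh] = None,
) -> Optional[FitResult]:
    """Best valid hypothesis over ``n_hypo`` independent RANSAC draws.

    Sub-seeds are derived deterministically from ``seed`` and the hypothesis
    index, so runs are reproducible and hypotheses are independent.
    Returns ``None`` when the cluster is too small or no hypothesis reaches
    the inlier-validity threshold.
    """
    cfg = cfg or RansacConfig()
    X = _positions(cluster)
    if len(X) < cfg.min_cluster_points:
        return None
    best: Optional[FitResult] = None
    for h in range(cfg.n_hypo):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), h]))
        res = generate_hypothesis(X, cfg, rng, template)
        if res is not None and res.valid and (best is None or res.chamfer < best.chamfer):
            best = res
    return best
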