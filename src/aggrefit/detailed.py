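"""Final per-cluster refinement with per-axis scaling and rotation.

After merging stabilizes, each cluster's best RANSAC sphere seeds a richer
coordinate-descent search whose state is (center, per-axis scales,
rotation). Each iteration evaluates, around the current state, the union of

* the 6 single-step translations (plus staying put),
* single-axis scale moves drawn from the scale-factor set,
* the 6 rotation increments of +/- the rotation step about each axis,

scored by the symmetric chamfer distance against all cluster points, and
adopts the best strictly-improving move. Rotation increments accumulate, so
orientations beyond one step are reachable over iterations; the composed
matrix is re-orthonormalized after every update. Stopping criteria are the
same three as in local refinement, so the chamfer trace never increases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .fitting import FitResult, RansacConfig, SphereModel, chamfer_distance, _default_template
from .io import ComponentMesh, PointCloud, placed_vertices
from .nonspherical import rotation_variants

__all__ = ["FittedComponent", "detailed_fit"]

# per-axis scales are clamped to this window (times the initial radius) to
# prevent degenerate flattening on sparse or one-sided clusters
SCALE_CLAMP = (0.4, 2.5)


@dataclass
class FittedComponent:
    """A fully fitted component: affine placement of the template mesh."""

    center: np.ndarray
    axis_scales: np.ndarray
    rotation: np.ndarray
    chamfer: float
    source_cluster: int = -1
    iterations_used: int = 0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.axis_scales = np.asarray(self.axis_scales, dtype=np.float64)
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        if np.any(self.axis_scales <= 0):
            raise ValueError("axis_scales must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def placed(self, template: ComponentMesh) -> ComponentMesh:
        return template.placed(self.center, self.axis_scales, self.rotation)

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "axis_scales": self.axis_scales.tolist(),
            "rotation": self.rotation.tolist(),
            "chamfer": self.chamfer,
            "source_cluster": self.source_cluster,
            "iterations_used": self.iterations_used,
        }


def _reorthonormalize(R: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(R)
    out = u @ vt
    if np.linalg.det(out) < 0:
        u[:, -1] *= -1
        out = u @ vt
    return out


def detailed_fit(
    cluster: Union[np.ndarray, PointCloud],
    init: Union[FitResult, SphereModel],
    template: Optional[ComponentMesh] = None,
    cfg: Optional[RansacConfig] = None,
    source_cluster: int = -1,
) -> FittedComponent:
    """Coordinate-descent refinement of translation, per-axis scale, rotation."""
    cfg = cfg or RansacConfig()
    template = template or _default_template(cfg.template_subdivisions)
    X = cluster.positions if isinstance(cluster, PointCloud) else np.asarray(cluster, float)
    if len(X) == 0:
        raise ValueError("cluster must be non-empty")
    if isinstance(init, FitResult):
        center = init.sphere.center.copy()
        radius = init.sphere.radius
        R = np.asarray(init.rotation, dtype=np.float64).copy()
    else:
        center = init.center.copy()
        radius = init.radius
        R = np.eye(3)
    scales = np.full(3, radius)
    clamp_lo, clamp_hi = SCALE_CLAMP[0] * radius, SCALE_CLAMP[1] * radius

    def score(c, s, rot):
        return chamfer_distance(X, placed_vertices(template.vertices, c, s, rot))

    best = score(center, scales, R)
    iterations = 0
    rot_moves = rotation_variants(cfg.rotation_step_deg)[1:]
    scale_moves = [f for f in cfg.scale_factors if f != 1.0]
    for _ in range(cfg.n_refi):
        iterations += 1
        candidates: list[tuple[float, tuple]] = []
        # translations
        for axis in range(3):
            for sign in (+1.0, -1.0):
                c2 = center.copy()
                c2[axis] += sign * cfg.translation_step
                candidates.append((score(c2, scales, R), ("t", c2)))
        # single-axis scalings
        for axis in range(3):
            for f in scale_moves:
                s2 = scales.copy()
                s2[axis] = float(np.clip(s2[axis] * f, clamp_lo, clamp_hi))
                if s2[axis] == scales[axis]:
                    continue
                candidates.append((score(center, s2, R), ("s", s2)))
        # rotations
        for rv in rot_moves:
            R2 = _reorthonormalize(rv @ R)
            candidates.append((score(center, scales, R2), ("r", R2)))
        vals = np.array([v for v, _ in candidates])
        j = int(np.argmin(vals))
        cand_val = float(vals[j])
        improvement = best - cand_val
        if cand_val < best:
            kind, payload = candidates[j][1]
            if kind == "t":
                center = payload
            elif kind == "s":
                scales = payload
            else:
                R = payload
            best = cand_val
        if best < cfg.d_th1:
            break
        if improvement < cfg.d_th2:
            break
    return FittedComponent(
        center=center,
        axis_scales=scales,
        rotation=R,
        chamfer=best,
        source_cluster=source_cluster,
        iterations_used=iterations,
    )
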