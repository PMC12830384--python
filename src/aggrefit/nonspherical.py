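"""Extensions for ellipsoidal and slightly deformed component templates.

The base pipeline assumes spherical components, which makes the inlier test
(point-to-sphere distance) and the merge test (center distance vs. radius
sum) analytic. For general templates three replacements are used:

* :func:`vertex_inlier_fraction` — the fraction of placed template vertices
  lying within a threshold of the cluster; this generalizes the inlier
  criterion (the 50% validity rule is applied to this fraction).
* :func:`rotation_variants` / :func:`rotated_hypotheses` — the 7-member
  rotation set (identity plus +/-10 degrees about each coordinate axis)
  used both to extend hypothesis generation and in detailed fitting.
* :func:`inside_fraction` / :func:`nonspherical_merge_test` — two placed
  components are merged when more than n% of either's vertices lie strictly
  inside the other (n = 2 works well for ellipsoids, n = 10 for deformed
  spheres).

Inside/outside queries use the generalized winding number of the watertight
template mesh (sum of signed solid angles over the faces), which is exact
up to floating point for closed meshes; points on the surface score 1/2 and
are therefore not counted as inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import MeshNotWatertightError
from .io import ComponentMesh, PointCloud

__all__ = [
    "NonsphericalConfig",
    "vertex_inlier_fraction",
    "rotation_variants",
    "rotated_hypotheses",
    "generalized_winding_number",
    "inside_fraction",
    "nonspherical_merge_test",
]


@dataclass
class NonsphericalConfig:
    """Thresholds for the generalized (mesh-template) criteria."""

    vertex_inlier_threshold: float = 0.015  # reuses epsilon
    min_vertex_inlier_fraction: float = 0.35  # below (1 - occlusion)/2 coverage
    merge_inside_fraction_percent: float = 2.0  # 2 for ellipsoid, 10 for deformed
    rotation_step_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.vertex_inlier_threshold <= 0:
            raise ValueError("vertex_inlier_threshold must be positive")
        if not 0 < self.min_vertex_inlier_fraction < 1:
            raise ValueError("min_vertex_inlier_fraction must be in (0, 1)")
        if not 0 < self.merge_inside_fraction_percent < 100:
            raise ValueError("merge_inside_fraction_percent must be in (0, 100)")


def _points(x) -> np.ndarray:
    if isinstance(x, PointCloud):
        return x.positions
    if isinstance(x, ComponentMesh):
        return x.vertices
    return np.asarray(x, dtype=np.float64)


def vertex_inlier_fraction(placed_template, cluster, threshold: float) -> float:
    """Fraction of template vertices strictly within ``threshold`` of the cluster."""
    verts = _points(placed_template)
    pts = _points(cluster)
    if len(verts) == 0 or len(pts) == 0:
        raise ValueError("both vertex and point sets must be non-empty")
    d, _ = cKDTree(pts).query(verts)
    return float((d < threshold).mean())


def _axis_rotation(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    if axis == 1:  # y-axis has the opposite off-diagonal sign pattern
        m[i, j] = s
        m[j, i] = -s
    else:
        m[i, j] = -s
        m[j, i] = s
    return m


def rotation_variants(angle_deg: float = 10.0) -> list[np.ndarray]:
    """The 7 rotation moves: identity, then +/-angle about x, y, z."""
    a = np.deg2rad(angle_deg)
    out = [np.eye(3)]
    for axis in range(3):
        for sign in (+1.0, -1.0):
            out.append(_axis_rotation(axis, sign * a))
    return out


def rotated_hypotheses(base: np.ndarray | None = None, angle_deg: float = 10.0) -> list[np.ndarray]:
    """Seven pose variants of a base rotation: identity move first."""
    base = np.eye(3) if base is None else np.asarray(base, dtype=np.float64)
    return [v @ base for v in rotation_variants(angle_deg)]


def generalized_winding_number(points: np.ndarray, mesh: ComponentMesh) -> np.ndarray:
    """Winding number of each query point w.r.t. the closed mesh.

    Uses the van Oosterom-Strackee signed solid angle per triangle; for a
    watertight mesh the result is ~1 for interior points, ~0 for exterior
    points, and ~1/2 on the surface.
    """
    pts = _points(points)
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    a = tri[None, :, 0, :] - pts[:, None, :]  # (N, F, 3)
    b = tri[None, :, 1, :] - pts[:, None, :]
    c = tri[None, :, 2, :] - pts[:, None, :]
    la = np.linalg.norm(a, axis=2)
    lb = np.linalg.norm(b, axis=2)
    lc = np.linalg.norm(c, axis=2)
    num = np.einsum("nfd,nfd->nf", a, np.cross(b, c))
    den = (
        la * lb * lc
        + np.einsum("nfd,nfd->nf", a, b) * lc
        + np.einsum("nfd,nfd->nf", b, c) * la
        + np.einsum("nfd,nfd->nf", c, a) * lb
    )
    omega = 2.0 * np.arctan2(num, den)
    return omega.sum(axis=1) / (4.0 * np.pi)


def _require_watertight(mesh: ComponentMesh, name: str) -> None:
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise MeshNotWatertightError(f"{name} mesh is not watertight")


def inside_fraction(a: ComponentMesh, b: ComponentMesh) -> float:
    """Fraction of a's vertices strictly inside the watertight mesh b.

    Points on b's surface (winding number 1/2) are not inside, so two
    coincident meshes give 0.0.
    """
    _require_watertight(b, "containing")
    w = generalized_winding_number(a.vertices, b)
    return float((w > 0.5 + 1e-9).mean())


def nonspherical_merge_test(
    a: ComponentMesh, b: ComponentMesh, cfg: NonsphericalConfig | None = None
) -> bool:
    """True when either component buries more than n% of its vertices in the other."""
    cfg = cfg or NonsphericalConfig()
    frac = max(inside_fraction(a, b), inside_fraction(b, a))
    return frac > cfg.merge_inside_fraction_percent / 100.0
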