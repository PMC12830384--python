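"""Ground-truthed synthetic aggregates emulating SfM point clouds.

Real inputs to the segmentation pipeline are multi-view-stereo
reconstructions of things like grape bunches: dense but noisy surface
samples with missing regions where berries touch each other or face away
from every camera. This module builds such data from first principles so
every downstream stage can be tested against known component parameters:

* :func:`generate_packing` packs near-spherical components into a connected,
  grape-bunch-like arrangement around a vertical axis (neighbors touch, no
  deep interpenetration) and rescales the arrangement to span roughly the
  ``[-1, 1]`` cube, so radii are already expressed in normalized units.
* :func:`sample_surface` draws surface points at a fixed areal density, then
  applies contact occlusion (points buried inside a neighboring component),
  a spherical-cap occlusion per component (camera shadowing), and isotropic
  Gaussian noise.

Everything is driven by explicit seeds; identical seeds give identical
aggregates and clouds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmptyCloudError, PackingError
from .io import PointCloud

__all__ = [
    "DeformField",
    "GroundTruthComponent",
    "GroundTruthAggregate",
    "generate_packing",
    "sample_surface",
    "save_ground_truth",
    "load_ground_truth",
]

# Default study conditions for the generator: normalized radii comparable to
# real berries in a bunch, SfM-like noise about a third of the inlier
# threshold, a fifth of each surface hidden, and enough areal density to
# yield a few thousand raw points per component (matching typical
# photogrammetric cloud sizes of 1e3-1e4 points per component).
DEFAULT_NOISE_SD = 0.005
DEFAULT_OCCLUSION_FRACTION = 0.2
DEFAULT_DENSITY = 12000.0  # points per unit surface area


@dataclass
class DeformField:
    """Smooth radial perturbation for 'deformed' spherical components.

    The radius along unit direction d (component frame) is
    ``r * (1 + amplitude * sum_j w_j * P2(d . u_j))`` with ``sum |w_j| = 1``
    and P2 the second Legendre polynomial, so the bump field is low-frequency
    and bounded by ``amplitude`` (default well under 10% of the radius).
    """

    directions: np.ndarray  # (m, 3) unit vectors
    weights: np.ndarray  # (m,), sum of absolute values == 1
    amplitude: float = 0.08

    def radial_factor(self, dirs: np.ndarray) -> np.ndarray:
        dots = np.asarray(dirs) @ self.directions.T  # (n, m)
        p2 = 1.5 * dots**2 - 0.5
        return 1.0 + self.amplitude * (p2 @ self.weights)

    @classmethod
    def random(cls, rng: np.random.Generator, amplitude: float = 0.08, m: int = 3) -> "DeformField":
        dirs = rng.normal(size=(m, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        w = rng.uniform(-1.0, 1.0, size=m)
        w /= np.abs(w).sum()
        return cls(dirs, w, amplitude)


@dataclass
class GroundTruthComponent:
    """One true component: center, per-axis radii, rotation, optional bumps."""

    center: np.ndarray
    radii: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    deform: Optional[DeformField] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def bounding_radius(self) -> float:
        r = float(self.radii.max())
        if self.deform is not None:
            r *= 1.0 + self.deform.amplitude
        return r

    def surface_radius(self, dirs_local: np.ndarray) -> np.ndarray:
        """Radial surface distance along local unit directions (sphere/deformed)."""
        r = float(self.radii[0])
        if self.deform is None:
            return np.full(len(dirs_local), r)
        return r * self.deform.radial_factor(dirs_local)

    def contains(self, points: np.ndarray, shrink: float = 1.0) -> np.ndarray:
        """Boolean mask of world points strictly inside the component surface."""
        local = (np.asarray(points) - self.center) @ self.rotation
        if self.deform is None:
            q = local / self.radii
            return (q**2).sum(axis=1) < shrink**2
        norms = np.linalg.norm(local, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        dirs = local / safe[:, None]
        return norms < shrink * self.surface_radius(dirs)


@dataclass
class GroundTruthAggregate:
    """True components plus the sampling conditions used to emulate SfM."""

    components: list[GroundTruthComponent]
    noise_sd: float = DEFAULT_NOISE_SD
    occlusion_fraction: float = DEFAULT_OCCLUSION_FRACTION
    density_per_component: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("aggregate needs at least one component")
        if not 0.0 <= self.occlusion_fraction < 1.0:
            raise ValueError("occlusion_fraction must be in [0, 1)")

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.components])

    @property
    def min_radius(self) -> float:
        return float(min(c.radii.min() for c in self.components))


def _rescale(components: list[GroundTruthComponent]) -> None:
    """Uniformly rescale and recenter so the sphere-union bbox spans [-1, 1]."""
    centers = np.array([c.center for c in components])
    radii = np.array([c.bounding_radius for c in components])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    mid = (lo + hi) / 2.0
    scale = 2.0 / float((hi - lo).max())
    for c in components:
        c.center = (c.center - mid) * scale
        c.radii = c.radii * scale


def _bunch_elongation(n_components: int) -> tuple[float, float]:
    """Axial direction bias and lateral cap factor as functions of count.

    Larger bunches are packed wider and less axially stretched; the
    interpolation keeps the normalized component radii near the requested
    range after the final rescale into the [-1, 1] cube (the normalized
    radius of a connected bunch is fixed by its count and elongation, not
    by the drawn radii).
    """
    z_bias = float(np.clip(5.5 - 0.18 * n_components, 2.2, 4.2))
    lateral = float(np.clip(0.55 + 0.062 * n_components, 1.0, 2.0))
    return z_bias, lateral


def _pack_once(
    n_components: int,
    radius_range: tuple[float, float],
    shape: str,
    rng: np.random.Generator,
    max_attempts: int,
    contact_range: tuple[float, float],
    z_bias: float,
    lateral_cap: float,
) -> list[GroundTruthComponent]:
    r_lo, r_hi = radius_range

    def make_component(center: np.ndarray) -> GroundTruthComponent:
        r = rng.uniform(r_lo, r_hi)
        if shape == "sphere":
            return GroundTruthComponent(center, np.array([r, r, r]))
        if shape == "ellipsoid":
            elong = rng.uniform(1.25, 1.45)
            rot = Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31 - 1))
            ).as_matrix()
            return GroundTruthComponent(center, np.array([r, r, r * elong]), rot)
        return GroundTruthComponent(center, np.array([r, r, r]), deform=DeformField.random(rng))

    components = [make_component(np.zeros(3))]
    for _ in range(1, n_components):
        placed = False
        for _attempt in range(max_attempts):
            # anchors at the bunch tips are preferred part of the time so the
            # arrangement elongates along the axis like a real bunch
            if rng.uniform() < 0.3:
                zs = np.array([abs(c.center[2]) for c in components])
                anchor = components[int(np.argmax(zs))]
            else:
                anchor = components[rng.integers(len(components))]
            direction = rng.normal(size=3) * np.array([1.0, 1.0, z_bias])
            direction /= np.linalg.norm(direction)
            cand = make_component(np.zeros(3))
            gap = rng.uniform(*contact_range) * (
                anchor.bounding_radius + cand.bounding_radius
            )
            center = anchor.center + direction * gap
            if np.linalg.norm(center[:2]) > lateral_cap:
                continue
            cand.center = center
            ok = True
            for other in components:
                d = np.linalg.norm(center - other.center)
                if d < 0.95 * (other.bounding_radius + cand.bounding_radius):
                    ok = False
                    break
            if ok:
                components.append(cand)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place component {len(components) + 1} of "
                f"{n_components}; try fewer or smaller components"
            )
    return components


def generate_packing(
    n_components: int,
    radius_range: tuple[float, float] = (0.08, 0.15),
    shape: str = "sphere",
    seed: int = 0,
    max_attempts: int = 4000,
    contact_range: tuple[float, float] = (0.95, 1.0),
    rescale: bool = True,
    n_arrangements: int = 12,
    **aggregate_kwargs,
) -> GroundTruthAggregate:
    """Pack components into a connected bunch by sequential rejection sampling.

    Each new component is placed in contact with a randomly chosen anchor
    (center distance drawn in ``contact_range`` times the sum of bounding
    radii), with directions biased along the vertical axis so the
    arrangement elongates like a real bunch. A placement is accepted only
    if every pairwise center distance stays at or above 0.95 times the
    corresponding radius sum (no deep interpenetration).

    With ``rescale=True`` the finished bunch is uniformly scaled to span
    the ``[-1, 1]`` cube, so the returned radii are in normalized units.
    Because that rescale changes the radii, ``n_arrangements`` candidate
    packings are drawn (deterministically from the seed) and the one whose
    rescaled radii best match ``radius_range`` is kept.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    r_lo, r_hi = radius_range
    if not (0 < r_lo <= r_hi):
        raise ValueError("radius_range must satisfy 0 < min <= max")
    if shape not in {"sphere", "ellipsoid", "deformed"}:
        raise ValueError(f"unknown shape: {shape}")
    z_bias, lateral = _bunch_elongation(n_components)
    lateral_cap = lateral * r_hi

    if not rescale or n_components == 1:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101, 0]))
        components = _pack_once(
            n_components, radius_range, shape, rng, max_attempts, contact_range,
            z_bias, lateral_cap,
        )
        return GroundTruthAggregate(components, **aggregate_kwargs)

    best: Optional[list[GroundTruthComponent]] = None
    best_score = np.inf
    first_error: Optional[PackingError] = None
    for arrangement in range(max(1, n_arrangements)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101, arrangement]))
        try:
            components = _pack_once(
                n_components, radius_range, shape, rng, max_attempts, contact_range,
                z_bias, lateral_cap,
            )
        except PackingError as exc:
            first_error = first_error or exc
            continue
        _rescale(components)
        radii = np.array([c.radii.min() for c in components])
        score = max(0.0, float(radii.max()) - r_hi) + max(0.0, r_lo - float(radii.min()))
        if score < best_score:
            best, best_score = components, score
    if best is None:
        raise first_error or PackingError("packing failed for every arrangement")
    return GroundTruthAggregate(best, **aggregate_kwargs)


def _sphere_area(radii: np.ndarray) -> float:
    """Surface area; Thomsen's approximation for ellipsoids."""
    a, b, c = radii
    if np.allclose(radii, radii[0]):
        return float(4.0 * np.pi * a**2)
    p = 1.6075
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return float(4.0 * np.pi * s ** (1.0 / p))


def _sample_component_surface(
    comp: GroundTruthComponent, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform samples on the component surface, in world coordinates."""
    if comp.deform is None and not np.allclose(comp.radii, comp.radii[0]):
        # ellipsoid: sample directions, keep with probability proportional to
        # the local area element so the density is uniform over the surface
        pts = []
        a, b, c = comp.radii
        needed = n
        while needed > 0:
            m = max(4 * needed, 128)
            d = rng.normal(size=(m, 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            x, y, z = d[:, 0], d[:, 1], d[:, 2]
            w = np.sqrt((a * y * z) ** 2 + (b * x * z) ** 2 + (c * x * y) ** 2)
            keep = rng.uniform(0, w.max(), size=m) < w
            sel = d[keep][:needed]
            pts.append(sel * comp.radii)
            needed -= len(sel)
        local = np.vstack(pts)
    else:
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        local = d * comp.surface_radius(d)[:, None]
    return local @ comp.rotation.T + comp.center


def sample_surface(
    aggregate: GroundTruthAggregate, seed: int = 0
) -> tuple[PointCloud, GroundTruthAggregate]:
    """Draw an SfM-like cloud from the aggregate; truth is returned unchanged.

    Per component: uniform surface samples at ``density_per_component``
    points per unit area; points strictly inside a neighboring component
    are removed (contact occlusion); a random spherical cap covering
    ``occlusion_fraction`` of the directions is removed (camera shadowing);
    finally isotropic Gaussian noise of sd ``noise_sd`` is added to every
    surviving point.
    """
    kept = []
    for i, comp in enumerate(aggregate.components):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 211, i]))
        n = int(round(aggregate.density_per_component * _sphere_area(comp.radii)))
        n = max(n, 8)
        pts = _sample_component_surface(comp, n, rng)
        mask = np.ones(len(pts), dtype=bool)
        for j, other in enumerate(aggregate.components):
            if j == i:
                continue
            # cheap reject: only neighbors can swallow points
            if (
                np.linalg.norm(comp.center - other.center)
                > comp.bounding_radius + other.bounding_radius
            ):
                continue
            mask &= ~other.contains(pts)
        if aggregate.occlusion_fraction > 0.0:
            cap_dir = rng.normal(size=3)
            cap_dir /= np.linalg.norm(cap_dir)
            rel = pts - comp.center
            norms = np.linalg.norm(rel, axis=1)
            cosang = (rel @ cap_dir) / np.where(norms > 0, norms, 1.0)
            mask &= cosang <= 1.0 - 2.0 * aggregate.occlusion_fraction
        kept.append(pts[mask])
    all_pts = np.vstack([p for p in kept if len(p)]) if any(len(p) for p in kept) else None
    if all_pts is None or len(all_pts) == 0:
        raise EmptyCloudError("every sampled point was occluded")
    if aggregate.noise_sd > 0.0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
        all_pts = all_pts + noise_rng.normal(0.0, aggregate.noise_sd, size=all_pts.shape)
    return PointCloud(all_pts), aggregate


# ---------------------------------------------------------------------------
# ground-truth serialization
# ---------------------------------------------------------------------------


def save_ground_truth(aggregate: GroundTruthAggregate, path: str | Path) -> None:
    """Write the aggregate's true parameters as structured JSON."""
    payload = {
        "noise_sd": aggregate.noise_sd,
        "occlusion_fraction": aggregate.occlusion_fraction,
        "density_per_component": aggregate.density_per_component,
        "components": [
            {
                "center": c.center.tolist(),
                "radii": c.radii.tolist(),
                "rotation": c.rotation.tolist(),
                "deform": None
                if c.deform is None
                else {
                    "directions": c.deform.directions.tolist(),
                    "weights": c.deform.weights.tolist(),
                    "amplitude": c.deform.amplitude,
                },
            }
            for c in aggregate.components
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_ground_truth(path: str | Path) -> GroundTruthAggregate:
    payload = json.loads(Path(path).read_text())
    comps = []
    for c in payload["components"]:
        deform = None
        if c.get("deform"):
            deform = DeformField(
                np.asarray(c["deform"]["directions"]),
                np.asarray(c["deform"]["weights"]),
                float(c["deform"]["amplitude"]),
            )
        comps.append(
            GroundTruthComponent(
                np.asarray(c["center"]),
                np.asarray(c["radii"]),
                np.asarray(c["rotation"]),
                deform,
            )
        )
    return GroundTruthAggregate(
        comps,
        noise_sd=float(payload["noise_sd"]),
        occlusion_fraction=float(payload["occlusion_fraction"]),
        density_per_component=float(payload["density_per_component"]),
    )
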