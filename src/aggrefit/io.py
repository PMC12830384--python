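"""Point-cloud and mesh I/O plus geometric preprocessing.

This module holds the passive data containers (:class:`PointCloud`,
:class:`ComponentMesh`) and the three preprocessing steps applied to every
input cloud before clustering:

1. optional color / spatial filtering to isolate the aggregate,
2. normalization into the ``[-1, 1]`` cube (uniform scale, so sphericity of
   the components is preserved),
3. voxel-grid downsampling, replacing all points in each occupied voxel by
   their centroid.

Point clouds are read from PLY (ASCII or binary, via trimesh) or
whitespace-separated ``x y z [r g b]`` text. Meshes are read/written through
trimesh (OBJ/PLY). All exported meshes are mapped back into the input
cloud's original coordinate frame through the recorded normalization
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import trimesh

from .errors import (
    ConfigurationError,
    DegenerateCloudError,
    EmptyCloudError,
    OutOfBoundsError,
    ParseError,
)

__all__ = [
    "PointCloud",
    "ComponentMesh",
    "VoxelGridSpec",
    "NormalizationTransform",
    "read_pointcloud",
    "write_pointcloud",
    "normalize_pointcloud",
    "voxel_downsample",
    "filter_cloud",
    "hsv_range_predicate",
    "read_mesh",
    "write_component_meshes",
]


@dataclass
class PointCloud:
    """Positions (N, 3) with optional per-point RGB colors in [0, 1]."""

    positions: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.positions) == 0:
            raise EmptyCloudError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64)
            if self.colors.shape != self.positions.shape:
                raise ValueError("colors must have the same shape as positions")
            if self.colors.min() < 0.0 or self.colors.max() > 1.0:
                raise ValueError("colors must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at the given integer or boolean index, order preserved."""
        colors = None if self.colors is None else self.colors[index]
        return PointCloud(self.positions[index], colors)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions.min(axis=0), self.positions.max(axis=0)

    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds()
        return float(np.linalg.norm(hi - lo))


@dataclass
class ComponentMesh:
    """Triangle mesh used as the single-component template.

    The default template is a unit icosphere; its vertices lie on the unit
    sphere, which lets the fitting stage treat uniform scaling as a radius.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3 or len(self.vertices) == 0:
            raise ValueError("vertices must have shape (V, 3), V >= 1")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3 or len(self.faces) == 0:
            raise ValueError("faces must have shape (F, 3), F >= 1")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @classmethod
    def unit_sphere(cls, subdivisions: int = 2) -> "ComponentMesh":
        """Icosphere template; subdivision level 2 gives 162 vertices."""
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        verts = np.asarray(ico.vertices, dtype=np.float64)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        return cls(verts, np.asarray(ico.faces))

    def placed(
        self,
        center: np.ndarray,
        scales: np.ndarray | float,
        rotation: Optional[np.ndarray] = None,
    ) -> "ComponentMesh":
        """Return a copy with vertices mapped by v -> c + R (s * v)."""
        return ComponentMesh(
            placed_vertices(self.vertices, center, scales, rotation), self.faces.copy()
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def placed_vertices(
    vertices: np.ndarray,
    center: np.ndarray,
    scales: np.ndarray | float,
    rotation: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Apply (per-axis scale, rotation, translation) to template vertices."""
    v = vertices * np.asarray(scales, dtype=np.float64)
    if rotation is not None:
        v = v @ np.asarray(rotation, dtype=np.float64).T
    return v + np.asarray(center, dtype=np.float64)


@dataclass
class VoxelGridSpec:
    """Uniform grid over an axis-aligned box; default 200^3 over [-1, 1]^3."""

    resolution_per_axis: int = 200
    lower: np.ndarray = field(default_factory=lambda: np.array([-1.0, -1.0, -1.0]))
    upper: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 1.0]))

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=np.float64)
        self.upper = np.asarray(self.upper, dtype=np.float64)
        if self.resolution_per_axis < 1:
            raise ValueError("resolution_per_axis must be >= 1")
        if not np.any(self.upper > self.lower):
            raise ValueError("grid bounds must have positive extent on some axis")


@dataclass
class NormalizationTransform:
    """Record of the map x_norm = (x - offset) * scale and its inverse."""

    offset: np.ndarray
    scale: float

    def to_normalized(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.offset) * self.scale

    def to_original(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) / self.scale + self.offset

    @classmethod
    def identity(cls) -> "NormalizationTransform":
        return cls(np.zeros(3), 1.0)


def normalize_pointcloud(cloud: PointCloud) -> tuple[PointCloud, NormalizationTransform]:
    """Center on the bounding-box midpoint and scale the largest extent to [-1, 1].

    A single uniform scale is used for all axes so that spherical components
    stay spherical; the returned transform inverts the mapping for export.
    """
    lo, hi = cloud.bounds()
    extent = hi - lo
    max_extent = float(extent.max())
    if max_extent <= 0.0:
        raise DegenerateCloudError("cloud has zero extent; cannot normalize")
    offset = (lo + hi) / 2.0
    scale = 2.0 / max_extent
    transform = NormalizationTransform(offset, scale)
    return PointCloud(transform.to_normalized(cloud.positions), cloud.colors), transform


def voxel_downsample(cloud: PointCloud, grid: VoxelGridSpec | None = None) -> PointCloud:
    """Replace all points in each occupied voxel by their centroid.

    Voxel membership uses half-open intervals [lo, hi) per axis, with the
    final voxel closed so points on the upper boundary are kept. Output
    points are ordered by voxel linear index, making the operation
    deterministic and idempotent for a fixed grid.
    """
    grid = grid or VoxelGridSpec()
    pos = cloud.positions
    if np.any(pos < grid.lower - 1e-12) or np.any(pos > grid.upper + 1e-12):
        raise OutOfBoundsError("point outside voxel grid bounds")
    res = grid.resolution_per_axis
    edge = (grid.upper - grid.lower) / res
    # guard axes with zero extent (degenerate but allowed by VoxelGridSpec)
    edge = np.where(edge > 0, edge, 1.0)
    idx = np.floor((pos - grid.lower) / edge).astype(np.int64)
    idx = np.clip(idx, 0, res - 1)
    linear = (idx[:, 0] * res + idx[:, 1]) * res + idx[:, 2]
    uniq, inverse = np.unique(linear, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(np.float64)
    centroids = np.zeros((len(uniq), 3))
    np.add.at(centroids, inverse, pos)
    centroids /= counts[:, None]
    colors = None
    if cloud.colors is not None:
        colors = np.zeros((len(uniq), 3))
        np.add.at(colors, inverse, cloud.colors)
        colors /= counts[:, None]
        colors = np.clip(colors, 0.0, 1.0)
    return PointCloud(centroids, colors)


def filter_cloud(
    cloud: PointCloud,
    color_predicate: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    crop_box: Optional[tuple[Sequence[float], Sequence[float]]] = None,
) -> PointCloud:
    """Keep points passing both the color predicate and the crop box.

    ``color_predicate`` maps an (N, 3) RGB array to an (N,) boolean mask.
    ``crop_box`` is an inclusive (lower, upper) pair. Point order is
    preserved; the result may be empty (returned as a boolean-empty marker
    is impossible, so an all-false selection raises downstream when wrapped
    in a PointCloud — callers should check ``mask.any()`` via this function
    raising :class:`EmptyCloudError`).
    """
    mask = np.ones(len(cloud), dtype=bool)
    if color_predicate is not None:
        if cloud.colors is None:
            raise ConfigurationError("color predicate given but cloud has no colors")
        mask &= np.asarray(color_predicate(cloud.colors), dtype=bool)
    if crop_box is not None:
        lo = np.asarray(crop_box[0], dtype=np.float64)
        hi = np.asarray(crop_box[1], dtype=np.float64)
        mask &= np.all((cloud.positions >= lo) & (cloud.positions <= hi), axis=1)
    if not mask.any():
        raise EmptyCloudError("filtering removed every point")
    return cloud.select(mask)


def _rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    maxc = rgb.max(axis=1)
    minc = rgb.min(axis=1)
    v = maxc
    delta = maxc - minc
    s = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
    h = np.zeros(len(rgb))
    nonzero = delta > 0
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = (maxc - r) / delta
        gc = (maxc - g) / delta
        bc = (maxc - b) / delta
    h = np.where(nonzero & (maxc == r), bc - gc, h)
    h = np.where(nonzero & (maxc == g) & (maxc != r), 2.0 + rc - bc, h)
    h = np.where(nonzero & (maxc == b) & (maxc != r) & (maxc != g), 4.0 + gc - rc, h)
    h = (h / 6.0) % 1.0
    return np.stack([h, s, v], axis=1)


def hsv_range_predicate(
    h_range: tuple[float, float] = (0.0, 1.0),
    s_range: tuple[float, float] = (0.0, 1.0),
    v_range: tuple[float, float] = (0.0, 1.0),
) -> Callable[[np.ndarray], np.ndarray]:
    """Predicate accepting colors whose HSV components fall in closed ranges.

    Hue ranges with ``h_min > h_max`` wrap around 1.0 (useful for reds).
    Defaults accept everything.
    """

    def predicate(rgb: np.ndarray) -> np.ndarray:
        hsv = _rgb_to_hsv(rgb)
        h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
        if h_range[0] <= h_range[1]:
            h_ok = (h >= h_range[0]) & (h <= h_range[1])
        else:
            h_ok = (h >= h_range[0]) | (h <= h_range[1])
        return (
            h_ok
            & (s >= s_range[0])
            & (s <= s_range[1])
            & (v >= v_range[0])
            & (v <= v_range[1])
        )

    return predicate


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"ply", "xyz", "txt", "obj"}:
        return "xyz" if suffix == "txt" else suffix
    raise ParseError(f"cannot infer format from suffix {path.suffix!r}")


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) not in (3, 6):
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 or 6 columns, got {len(parts)}"
                )
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ParseError(f"{path}: line {lineno}: inconsistent column count")
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=np.float64)
    colors = None
    if data.shape[1] == 6:
        colors = data[:, 3:6]
        if colors.max() > 1.0:  # 0-255 convention
            colors = colors / 255.0
    return PointCloud(data[:, :3], colors)


def _read_ply_cloud(path: Path) -> PointCloud:
    try:
        loaded = trimesh.load(str(path), process=False)
    except Exception as exc:  # trimesh raises a mix of types
        raise ParseError(f"{path}: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    if verts.size == 0:
        raise ParseError(f"{path}: no vertices")
    colors = None
    raw = getattr(loaded, "colors", None)
    if raw is None and hasattr(loaded, "visual"):
        try:
            raw = loaded.visual.vertex_colors
        except Exception:
            raw = None
    raw = np.asarray(raw) if raw is not None else np.empty(0)
    if raw.ndim == 2 and len(raw) == len(verts):
        colors = raw[:, :3].astype(np.float64) / 255.0
    return PointCloud(verts, colors)


def read_pointcloud(path: str | Path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from PLY (ASCII/binary) or XYZ[RGB] text."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply_cloud(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ParseError(f"unsupported point-cloud format: {fmt}")


def write_pointcloud(cloud: PointCloud, path: str | Path, format: Optional[str] = None) -> None:
    """Write a cloud as ASCII PLY or XYZ[RGB] text."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        data = cloud.positions
        if cloud.colors is not None:
            data = np.hstack([data, cloud.colors])
        np.savetxt(path, data, fmt="%.9g")
        return
    if fmt != "ply":
        raise ParseError(f"unsupported point-cloud format: {fmt}")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if cloud.colors is not None:
            fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        if cloud.colors is None:
            for p in cloud.positions:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        else:
            rgb = np.clip(np.round(cloud.colors * 255), 0, 255).astype(int)
            for p, c in zip(cloud.positions, rgb):
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {c[0]} {c[1]} {c[2]}\n")


def read_mesh(path: str | Path) -> ComponentMesh:
    """Read a template mesh (OBJ or PLY) into a :class:`ComponentMesh`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return ComponentMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def write_component_meshes(
    components: Iterable,
    template: ComponentMesh,
    directory: str | Path,
    format: str = "obj",
    transform: Optional[NormalizationTransform] = None,
) -> list[Path]:
    """Write one mesh file per fitted component.

    Each component's (center, per-axis scales, rotation) is applied to the
    template and, when a normalization transform is given, the vertices are
    mapped back into the original input frame. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format not in {"obj", "ply"}:
        raise ValueError(f"unsupported mesh format: {format}")
    paths = []
    for i, comp in enumerate(components):
        verts = placed_vertices(
            template.vertices,
            np.asarray(comp.center),
            np.asarray(comp.axis_scales),
            np.asarray(comp.rotation),
        )
        if transform is not None:
            verts = transform.to_original(verts)
        mesh = trimesh.Trimesh(vertices=verts, faces=template.faces, process=False)
        out = directory / f"component_{i:03d}.{format}"
        mesh.export(str(out))
        paths.append(out)
    return paths
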