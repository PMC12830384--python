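"""End-to-end orchestration: preprocess -> cluster -> fit -> merge -> refine.

:func:`run_pipeline` executes the full stage order on a point cloud and
returns fitted components in both the normalized working frame and the
original input frame, plus an evaluation report when ground truth is
supplied. All randomness flows from a single master seed through a
documented tagging scheme (stage tag, cluster index, hypothesis index), so
identical configurations reproduce byte-identical JSON reports.

:func:`run_sensitivity_sweep` reruns the pipeline over a grid of cluster
counts (multiples of the true component count) and initial radii (multiples
of the smallest true component), the protocol used to probe how forgiving
the two user-set parameters are.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterSet, kmeans_cluster
from .detailed import FittedComponent, detailed_fit
from .errors import EmptyCloudError
from .evaluation import EvaluationReport, evaluate
from .fitting import RansacConfig, fit_component, sub_seed, _default_template
from .io import (
    ComponentMesh,
    NormalizationTransform,
    PointCloud,
    VoxelGridSpec,
    filter_cloud,
    hsv_range_predicate,
    normalize_pointcloud,
    read_mesh,
    read_pointcloud,
    voxel_downsample,
    write_component_meshes,
)
from .merging import merge_to_fixpoint
from .nonspherical import NonsphericalConfig, nonspherical_merge_test
from .synthetic import GroundTruthAggregate, sample_surface

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_sensitivity_sweep"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; numeric defaults are the method's standard values."""

    k: int = 20
    initial_radius: float = 0.1
    shape_mode: str = "sphere"  # sphere | ellipsoid | deformed
    voxel_resolution: int = 200
    seed: int = 0
    alpha: float = 0.9
    ransac: RansacConfig = field(default_factory=RansacConfig)
    nonspherical: NonsphericalConfig = field(default_factory=NonsphericalConfig)
    merge_inside_fraction_percent: Optional[float] = None  # default 2 (ellipsoid) / 10 (deformed)
    crop_box: Optional[tuple] = None
    hsv_ranges: Optional[tuple] = None  # ((h0,h1),(s0,s1),(v0,v1))
    max_merge_rounds: Optional[int] = None
    template_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.initial_radius <= 0:
            raise ValueError("initial_radius must be positive")
        if self.shape_mode not in {"sphere", "ellipsoid", "deformed"}:
            raise ValueError(f"unknown shape_mode: {self.shape_mode}")

    def resolved_ransac(self) -> RansacConfig:
        cfg = dataclasses.replace(self.ransac, initial_radius=self.initial_radius)
        if self.shape_mode != "sphere":
            cfg = dataclasses.replace(cfg, rotate_hypotheses=True, vertex_inlier=True)
        return cfg

    def resolved_merge_percent(self) -> float:
        if self.merge_inside_fraction_percent is not None:
            return self.merge_inside_fraction_percent
        return 10.0 if self.shape_mode == "deformed" else 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ransac"]["scale_factors"] = list(d["ransac"]["scale_factors"])
        return d


@dataclass
class PipelineResult:
    components: list[FittedComponent]  # normalized frame
    components_original: list[FittedComponent]  # input frame
    transform: NormalizationTransform
    clusters: ClusterSet
    evaluation: Optional[EvaluationReport]
    log: dict
    config: PipelineConfig
    template: ComponentMesh

    @property
    def n_found(self) -> int:
        return len(self.components)

    def to_report(self) -> dict:
        report = {
            "config": self.config.to_dict(),
            "n_found": self.n_found,
            "components": [c.to_dict() for c in self.components_original],
            "log": self.log,
        }
        if self.evaluation is not None:
            report["evaluation"] = self.evaluation.to_dict()
        return report

    def to_json(self) -> str:
        return json.dumps(self.to_report(), sort_keys=True, indent=2)

    def write_meshes(self, directory, format: str = "obj") -> list[Path]:
        return write_component_meshes(
            self.components, self.template, directory, format, self.transform
        )


def _load_template(cfg: PipelineConfig) -> ComponentMesh:
    if cfg.template_path is not None:
        return read_mesh(cfg.template_path)
    return _default_template(cfg.ransac.template_subdivisions)


def run_pipeline(
    cloud: PointCloud | str | Path,
    cfg: PipelineConfig,
    truth: Optional[GroundTruthAggregate] = None,
    template: Optional[ComponentMesh] = None,
) -> PipelineResult:
    """Run the full segmentation pipeline on one aggregate cloud."""
    if not isinstance(cloud, PointCloud):
        cloud = read_pointcloud(cloud)
    predicate = None
    if cfg.hsv_ranges is not None:
        predicate = hsv_range_predicate(*cfg.hsv_ranges)
    if predicate is not None or cfg.crop_box is not None:
        cloud = filter_cloud(cloud, predicate, cfg.crop_box)
    input_diagonal = cloud.bbox_diagonal()
    n_input = len(cloud)

    normalized, transform = normalize_pointcloud(cloud)
    grid = VoxelGridSpec(resolution_per_axis=cfg.voxel_resolution)
    downsampled = voxel_downsample(normalized, grid)
    if len(downsampled) < cfg.k:
        raise EmptyCloudError(
            f"only {len(downsampled)} points after preprocessing; need >= k={cfg.k}"
        )

    template = template or _load_template(cfg)
    ransac = cfg.resolved_ransac()
    seed = int(cfg.seed)

    clusters = kmeans_cluster(downsampled, cfg.k, seed=sub_seed(seed, 1))
    fits = [
        fit_component(
            clusters.cloud.select(clusters.indices_of(i)),
            ransac,
            seed=sub_seed(seed, 2, i),
            template=template,
        )
        if len(clusters.indices_of(i)) > 0
        else None
        for i in range(clusters.k)
    ]

    predicate_merge = None
    if cfg.shape_mode != "sphere":
        ns_cfg = dataclasses.replace(
            cfg.nonspherical,
            merge_inside_fraction_percent=cfg.resolved_merge_percent(),
        )

        def predicate_merge(fa, fb):  # noqa: F811
            a = template.placed(fa.sphere.center, fa.sphere.radius, fa.rotation)
            b = template.placed(fb.sphere.center, fb.sphere.radius, fb.rotation)
            return nonspherical_merge_test(a, b, ns_cfg)

    clusters, fits, merge_log = merge_to_fixpoint(
        clusters,
        fits,
        ransac,
        seed=sub_seed(seed, 3),
        alpha=cfg.alpha,
        max_rounds=cfg.max_merge_rounds,
        template=template,
        predicate=predicate_merge,
    )

    components: list[FittedComponent] = []
    for i in range(clusters.k):
        fit = fits[i]
        if fit is None or not fit.valid:
            continue
        comp = detailed_fit(
            clusters.cloud.select(clusters.indices_of(i)),
            fit,
            template,
            ransac,
            source_cluster=i,
        )
        components.append(comp)

    components_original = [
        FittedComponent(
            center=transform.to_original(c.center),
            axis_scales=c.axis_scales / transform.scale,
            rotation=c.rotation,
            chamfer=c.chamfer / transform.scale,
            source_cluster=c.source_cluster,
            iterations_used=c.iterations_used,
        )
        for c in components
    ]

    evaluation = None
    evaluation_failed = False
    if truth is not None and components:
        try:
            evaluation = evaluate(truth, components_original, input_diagonal)
        except ValueError:  # no found component corresponds to any true one
            evaluation_failed = True

    log = {
        "n_input_points": n_input,
        "n_downsampled_points": len(downsampled),
        "initial_k": cfg.k,
        "final_k": clusters.k,
        "n_components": len(components),
        "merge_rounds": merge_log,
        "chamfers": [c.chamfer for c in components],
        "evaluation_failed": evaluation_failed,
    }
    return PipelineResult(
        components=components,
        components_original=components_original,
        transform=transform,
        clusters=clusters,
        evaluation=evaluation,
        log=log,
        config=cfg,
        template=template,
    )


def normalized_min_radius(cloud: PointCloud, truth: GroundTruthAggregate) -> float:
    """Smallest true component radius expressed in the normalized frame."""
    _, transform = normalize_pointcloud(cloud)
    return truth.min_radius * transform.scale


def run_sensitivity_sweep(
    aggregate: GroundTruthAggregate,
    seed: int = 0,
    k_multipliers: Sequence[float] = (1.0, 2.0, 3.0),
    radius_multipliers: Sequence[float] = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3),
    base_cfg: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Grid of pipeline runs over cluster-count and initial-radius factors.

    k is set to ``round(multiplier * N_e)`` and the initial radius to
    ``multiplier * r_min`` with ``r_min`` the smallest true radius in the
    normalized frame. One row per grid cell with the recovery metrics.
    """
    cloud, _ = sample_surface(aggregate, seed=seed)
    r_min = normalized_min_radius(cloud, aggregate)
    n_e = len(aggregate.components)
    base = base_cfg or PipelineConfig()
    rows = []
    for km in k_multipliers:
        for rm in radius_multipliers:
            cfg = dataclasses.replace(
                base,
                k=max(1, int(round(km * n_e))),
                initial_radius=rm * r_min,
                seed=seed,
            )
            result = run_pipeline(cloud, cfg, truth=aggregate)
            ev = result.evaluation
            rows.append(
                {
                    "k_multiplier": km,
                    "radius_multiplier": rm,
                    "k": cfg.k,
                    "initial_radius": cfg.initial_radius,
                    "n_true": n_e,
                    "n_found": result.n_found,
                    "m_d": np.nan if ev is None else ev.mean_center_distance,
                    "m_s": np.nan if ev is None else ev.sd_center_distance,
                }
            )
    return pd.DataFrame(rows)
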