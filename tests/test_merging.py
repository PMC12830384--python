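import numpy as np
import pytest

import aggrefit as ag
from aggrefit.fitting import FitResult, RansacConfig, SphereModel
from aggrefit.merging import build_overlap_edges, merge_step, merge_to_fixpoint, spheres_overlap
from conftest import sphere_surface_points


def make_fit(center, radius):
    return FitResult(
        sphere=SphereModel(np.asarray(center, float), radius),
        chamfer=0.01,
        inlier_ratio=1.0,
        valid=True,
        iterations_used=1,
    )


class TestSpheresOverlap:
    def test_overlap_just_below_threshold(self):
        a = SphereModel(np.zeros(3), 0.5)
        b = SphereModel(np.array([0.89, 0, 0]), 0.5)
        assert spheres_overlap(a, b, alpha=0.9)

    def test_boundary_is_strict(self):
        a = SphereModel(np.zeros(3), 0.5)
        b = SphereModel(np.array([0.9, 0, 0]), 0.5)
        assert not spheres_overlap(a, b, alpha=0.9)

    def test_concentric(self):
        a = SphereModel(np.zeros(3), 0.3)
        b = SphereModel(np.zeros(3), 0.1)
        assert spheres_overlap(a, b)


class TestMergeStep:
    def test_no_overlaps_is_identity(self, rng):
        pts = np.vstack(
            [sphere_surface_points((i * 2.0, 0, 0), 0.1, 50, seed=i) for i in range(3)]
        )
        cloud = ag.PointCloud(pts)
        labels = np.repeat([0, 1, 2], 50)
        clusters = ag.ClusterSet(labels, 3, cloud)
        fits = [make_fit((i * 2.0, 0, 0), 0.1) for i in range(3)]
        new_clusters, new_fits, changed = merge_step(clusters, fits, RansacConfig())
        assert not changed
        assert new_clusters.k == 3
        np.testing.assert_array_equal(new_clusters.labels, labels)

    def test_split_component_merges_to_one(self):
        # one true sphere split across two clusters; both fitted spheres overlap
        pts = sphere_surface_points((0, 0, 0), 0.1, 400, seed=3)
        cloud = ag.PointCloud(pts)
        labels = (pts[:, 0] > 0).astype(int)
        clusters = ag.ClusterSet(labels, 2, cloud)
        cfg = RansacConfig(initial_radius=0.1)
        fits = [make_fit((-0.02, 0, 0), 0.1), make_fit((0.02, 0, 0), 0.1)]
        new_clusters, new_fits, changed = merge_step(clusters, fits, cfg, seed=0)
        assert changed
        assert new_clusters.k == 1
        assert new_fits[0] is not None and new_fits[0].valid
        assert np.linalg.norm(new_fits[0].sphere.center) < 0.02

    def test_three_mutually_overlapping_recluster_at_two(self, rng):
        pts = rng.normal(scale=0.1, size=(300, 3))
        cloud = ag.PointCloud(pts)
        labels = rng.integers(0, 3, size=300)
        clusters = ag.ClusterSet(labels, 3, cloud)
        fits = [make_fit((0.01 * i, 0, 0), 0.1) for i in range(3)]
        new_clusters, _, changed = merge_step(clusters, fits, RansacConfig(), seed=0)
        assert changed
        assert new_clusters.k == 2  # m - 1

    def test_point_count_conserved(self, rng):
        pts = rng.normal(size=(200, 3))
        cloud = ag.PointCloud(pts)
        labels = rng.integers(0, 4, size=200)
        clusters = ag.ClusterSet(labels, 4, cloud)
        fits = [make_fit((0.005 * i, 0, 0), 0.1) for i in range(4)]
        new_clusters, _, _ = merge_step(clusters, fits, RansacConfig(), seed=0)
        assert len(new_clusters.labels) == 200
        assert np.all(new_clusters.labels >= 0)
        assert new_clusters.sizes().sum() == 200


class TestMergeToFixpoint:
    def test_non_overlapping_unchanged_after_one_round(self):
        pts = np.vstack(
            [sphere_surface_points((i * 3.0, 0, 0), 0.1, 60, seed=i) for i in range(2)]
        )
        cloud = ag.PointCloud(pts)
        clusters = ag.ClusterSet(np.repeat([0, 1], 60), 2, cloud)
        fits = [make_fit((0, 0, 0), 0.1), make_fit((3.0, 0, 0), 0.1)]
        out_clusters, _, log = merge_to_fixpoint(clusters, fits, RansacConfig(), seed=0)
        assert len(log) == 1 and not log[0]["changed"]
        assert out_clusters.k == 2

    def test_cluster_count_strictly_decreases_when_changed(self, rng):
        pts = rng.normal(scale=0.1, size=(400, 3))
        cloud = ag.PointCloud(pts)
        labels = rng.integers(0, 5, size=400)
        clusters = ag.ClusterSet(labels, 5, cloud)
        fits = [make_fit((0.01 * i, 0, 0), 0.1) for i in range(5)]
        _, _, log = merge_to_fixpoint(clusters, fits, RansacConfig(initial_radius=0.1), seed=0)
        for entry in log:
            if entry["changed"]:
                assert entry["k_after"] < entry["k_before"]

    def test_end_to_end_recovery_on_oversegmented_aggregate(self, small_aggregate, small_cloud):
        # 12-sphere aggregate clustered with k=24: merging should bring the
        # fitted-component count close to the true component count
        from aggrefit.pipeline import normalized_min_radius

        normalized, _ = ag.normalize_pointcloud(small_cloud)
        down = ag.voxel_downsample(normalized)
        clusters = ag.kmeans_cluster(down, 24, seed=0)
        cfg = RansacConfig(initial_radius=normalized_min_radius(small_cloud, small_aggregate))
        fits = [
            ag.fit_component(ag.extract_cluster(clusters, i), cfg, seed=i)
            for i in range(clusters.k)
        ]
        out_clusters, out_fits, log = merge_to_fixpoint(clusters, fits, cfg, seed=0)
        n_final = sum(1 for f in out_fits if f is not None and f.valid)
        assert abs(n_final - 12) <= 2
        assert out_clusters.sizes().sum() == len(down)
        assert len(log) <= 24
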