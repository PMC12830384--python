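import numpy as np
import pytest

import aggrefit as ag
from aggrefit.errors import MeshNotWatertightError
from aggrefit.nonspherical import (
    NonsphericalConfig,
    generalized_winding_number,
    inside_fraction,
    nonspherical_merge_test,
    rotation_variants,
    rotated_hypotheses,
    vertex_inlier_fraction,
)
from conftest import sphere_surface_points


class TestVertexInlierFraction:
    def test_dense_exact_surface_gives_one(self, unit_sphere_template):
        # threshold comfortably above the sampling spacing (~sqrt(4*pi/n))
        pts = sphere_surface_points((0, 0, 0), 1.0, 5000, seed=0)
        frac = vertex_inlier_fraction(unit_sphere_template, pts, threshold=0.15)
        assert frac == 1.0

    def test_far_displacement_gives_zero(self, unit_sphere_template):
        pts = sphere_surface_points((10, 0, 0), 1.0, 200, seed=1)
        assert vertex_inlier_fraction(unit_sphere_template, pts, threshold=0.05) == 0.0

    def test_hemisphere_coverage_about_half(self, unit_sphere_template):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(8000, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        d = d[d[:, 2] > 0]  # upper hemisphere only
        frac = vertex_inlier_fraction(unit_sphere_template, d, threshold=0.05)
        assert 0.4 < frac < 0.6

    def test_monotone_in_threshold(self, unit_sphere_template, rng):
        pts = rng.normal(size=(100, 3))
        fracs = [
            vertex_inlier_fraction(unit_sphere_template, pts, t) for t in (0.05, 0.2, 0.5, 2.0)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestRotationVariants:
    def test_seven_members_identity_first(self):
        variants = rotation_variants(10.0)
        assert len(variants) == 7
        np.testing.assert_array_equal(variants[0], np.eye(3))

    def test_each_nonidentity_rotates_by_exactly_ten_degrees(self):
        for R in rotation_variants(10.0)[1:]:
            # rotation angle from the trace: cos(theta) = (tr - 1) / 2
            angle = np.degrees(np.arccos((np.trace(R) - 1) / 2))
            assert angle == pytest.approx(10.0, abs=1e-9)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)

    def test_rotated_hypotheses_compose_with_base(self):
        rng = np.random.default_rng(0)
        from scipy.spatial.transform import Rotation

        base = Rotation.random(random_state=np.random.RandomState(1)).as_matrix()
        hyps = rotated_hypotheses(base, 10.0)
        assert len(hyps) == 7
        np.testing.assert_allclose(hyps[0], base, atol=1e-12)
        for h in hyps[1:]:
            np.testing.assert_allclose(h @ h.T, np.eye(3), atol=1e-12)


class TestInsideFraction:
    def test_coincident_meshes_zero(self, unit_sphere_template):
        assert inside_fraction(unit_sphere_template, unit_sphere_template) == 0.0

    def test_tiny_sphere_inside_large_is_one(self, unit_sphere_template):
        small = unit_sphere_template.placed(np.zeros(3), 0.1)
        assert inside_fraction(small, unit_sphere_template) == 1.0

    def test_center_on_locally_flat_surface_about_half(self, unit_sphere_template):
        # against a much larger sphere the surface is locally a plane, so a
        # small sphere centered on it dips half its vertices inside
        big = unit_sphere_template.placed(np.zeros(3), 100.0)
        small = unit_sphere_template.placed(np.array([100.0, 0, 0]), 1.0)
        frac = inside_fraction(small, big)
        assert 0.4 < frac < 0.6

    def test_equal_spheres_center_on_surface_lens_fraction(self, unit_sphere_template):
        # for equal unit spheres with centers one radius apart, the vertices
        # of one inside the other form the cap u.x < -1/2: exactly 1/4 of
        # the surface
        shifted = unit_sphere_template.placed(np.array([1.0, 0, 0]), 1.0)
        frac = inside_fraction(shifted, unit_sphere_template)
        assert frac == pytest.approx(0.25, abs=0.05)

    def test_disjoint_zero(self, unit_sphere_template):
        far = unit_sphere_template.placed(np.array([5.0, 0, 0]), 1.0)
        assert inside_fraction(far, unit_sphere_template) == 0.0

    def test_non_watertight_raises(self, unit_sphere_template):
        open_mesh = ag.ComponentMesh(
            unit_sphere_template.vertices, unit_sphere_template.faces[:-10]
        )
        with pytest.raises(MeshNotWatertightError):
            inside_fraction(unit_sphere_template, open_mesh)

    def test_winding_number_interior_exterior(self, unit_sphere_template):
        w_in = generalized_winding_number(np.array([[0.0, 0, 0], [0.3, 0.2, -0.1]]), unit_sphere_template)
        w_out = generalized_winding_number(np.array([[2.0, 0, 0], [0, 0, -1.5]]), unit_sphere_template)
        np.testing.assert_allclose(w_in, 1.0, atol=1e-9)
        np.testing.assert_allclose(w_out, 0.0, atol=1e-9)


class TestNonsphericalMergeTest:
    def test_disjoint_components_do_not_merge(self, unit_sphere_template):
        a = unit_sphere_template.placed(np.zeros(3), 1.0)
        b = unit_sphere_template.placed(np.array([5.0, 0, 0]), 1.0)
        assert not nonspherical_merge_test(a, b)

    def test_threshold_separates_two_from_ten_percent(self, unit_sphere_template):
        # place b so that a small but nonzero vertex fraction of a is inside
        a = unit_sphere_template.placed(np.array([1.82, 0.0, 0.0]), 1.0)
        b = unit_sphere_template
        frac = max(inside_fraction(a, b), inside_fraction(b, a))
        assert 0.02 < frac < 0.10
        assert nonspherical_merge_test(a, b, NonsphericalConfig(merge_inside_fraction_percent=2.0))
        assert not nonspherical_merge_test(
            a, b, NonsphericalConfig(merge_inside_fraction_percent=10.0)
        )

    def test_symmetric(self, unit_sphere_template):
        a = unit_sphere_template.placed(np.array([0.5, 0, 0]), 0.8)
        b = unit_sphere_template
        cfg = NonsphericalConfig()
        assert nonspherical_merge_test(a, b, cfg) == nonspherical_merge_test(b, a, cfg)
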