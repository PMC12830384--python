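import numpy as np
import pytest

import aggrefit as ag


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def unit_sphere_template():
    return ag.ComponentMesh.unit_sphere(subdivisions=2)


@pytest.fixture(scope="session")
def small_aggregate():
    """A 12-component spherical aggregate shared by slower integration tests.

    Component radii land around 0.09-0.15 in normalized units, the regime
    the fitting thresholds (translation step 0.01, epsilon 0.015) are
    scaled for.
    """
    return ag.generate_packing(12, seed=0)


@pytest.fixture(scope="session")
def small_cloud(small_aggregate):
    cloud, _ = ag.sample_surface(small_aggregate, seed=7)
    return cloud


def sphere_surface_points(center, radius, n, seed=0):
    """Exact surface samples of one sphere (no noise), for constructed fixtures."""
    r = np.random.default_rng(seed)
    d = r.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.asarray(center) + radius * d
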