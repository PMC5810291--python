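import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coalternet import GenerativeSpec, SyntheticRegion, VolumeGrid, make_toy_atlas

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_grid() -> VolumeGrid:
    """Tiny symmetric grid around the origin (2 mm, 21^3 voxels)."""
    return VolumeGrid(origin=(-20.0, -20.0, -20.0), voxel_size=2.0,
                      dims=(21, 21, 21))


@pytest.fixture
def two_region_spec() -> GenerativeSpec:
    """Two mirrored 10x10x10-voxel cuboids at 2 mm."""
    return GenerativeSpec(
        n_experiments=10,
        regions=[
            SyntheticRegion("Box_L", "L", (-10.0, 0.0, 0.0), (10.0, 10.0, 10.0)),
            SyntheticRegion("Box_R", "R", (10.0, 0.0, 0.0), (10.0, 10.0, 10.0)),
        ],
        couplings=[], seed=1)


@pytest.fixture
def two_region_atlas(two_region_spec):
    grid = VolumeGrid(origin=(-40.0, -40.0, -40.0), voxel_size=2.0,
                      dims=(41, 41, 41))
    return make_toy_atlas(two_region_spec, grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
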