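import numpy as np
import pytest

from seasonair import RegionSpec, generate_region
from seasonair.synthetic_region import distance_cells


@pytest.fixture(scope="session")
def noisefree_spec() -> RegionSpec:
    """Small noise-free region: every planted parameter exactly recoverable."""
    return RegionSpec(grid_shape=(40, 50), n_sectors=20, noise_sd=0.0,
                      cars_noise_sd=0.0, decay_scale=1.0, seed=11)


@pytest.fixture(scope="session")
def noisefree_region(noisefree_spec):
    return generate_region(noisefree_spec)


@pytest.fixture(scope="session")
def noisy_region():
    spec = RegionSpec(grid_shape=(40, 50), n_sectors=24, seed=7)
    return generate_region(spec)


@pytest.fixture(scope="session")
def road_distance(noisefree_spec):
    return distance_cells(noisefree_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
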