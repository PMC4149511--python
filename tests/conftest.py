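import numpy as np
import pytest

from gridrep import TerrainSpec, make_constant, make_gaussian_field, make_ramp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_raster():
    """5x5 km flat surface at 100 m (56x56 cells of 90 m)."""
    return make_constant(56, 56, 90.0, 100.0)


@pytest.fixture
def ramp_raster():
    """5x5 km east-west gradient, 0.02 m per m."""
    return make_ramp(56, 56, 90.0, 0.02, 0.0, 50.0)


@pytest.fixture
def field_raster():
    """Seeded correlated field, mean 159.5 m / SD 40 m."""
    return make_gaussian_field(TerrainSpec(seed=7))
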