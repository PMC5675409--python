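import numpy as np
import pytest

from grassnpp.raster_io import RasterGrid
from grassnpp.synthetic import WorldConfig, make_world


@pytest.fixture(scope="session")
def small_world():
    """A 10x10, 4-year world for fast unit tests."""
    return make_world(WorldConfig(seed=7, grid_shape=(10, 10), n_years=4))


@pytest.fixture(scope="session")
def demo_world():
    """The default 20x20, 13-year study-condition world."""
    return make_world(WorldConfig(seed=3))


@pytest.fixture
def grid10():
    return RasterGrid(rows=10, cols=10, origin_x=0.0, origin_y=5000.0,
                      pixel_size=500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
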