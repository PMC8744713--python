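import numpy as np
import pytest

from espsim import synthetic
from espsim.grids import BinaryMask, ContinuousGrid, LandUseGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_landuse(rng):
    """Small random (non-autocorrelated) land-use grid, all six classes."""
    return LandUseGrid(30.0, (0.0, 0.0), rng.integers(1, 7, (20, 20)))


@pytest.fixture(scope="session")
def landscape():
    """Medium autocorrelated landscape shared across read-only tests."""
    spec = synthetic.LandscapeSpec(shape=(120, 120), seed=7)
    return synthetic.generate_landscape(spec)


@pytest.fixture(scope="session")
def factors(landscape):
    return synthetic.generate_factors(landscape, seed=11)


def make_mask(bits, cell_size=30.0):
    return BinaryMask(cell_size, (0.0, 0.0), np.asarray(bits, dtype=bool))


def make_continuous(values, cell_size=30.0):
    return ContinuousGrid(cell_size, (0.0, 0.0), np.asarray(values, dtype=float))
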