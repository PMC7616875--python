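import numpy as np
import pytest

from pgsmap.grid import build_hex_grid
from pgsmap.spatial import contiguity_weights

SQUARE_10KM = (0.0, 0.0, 10_000.0, 10_000.0)
SQUARE_20KM = (0.0, 0.0, 20_000.0, 20_000.0)


@pytest.fixture(scope="session")
def grid300():
    """~300-node hexagonal grid on a 20 km square."""
    return build_hex_grid(SQUARE_20KM, target_n=300)


@pytest.fixture(scope="session")
def grid1000():
    return build_hex_grid(SQUARE_20KM, target_n=1000)


@pytest.fixture(scope="session")
def W300(grid300):
    return contiguity_weights(grid300)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
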