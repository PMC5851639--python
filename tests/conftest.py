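import numpy as np
import pytest

from rtwalk.grid import ObstaclesParams, build_grid, sample_connected_grid


@pytest.fixture(scope="session")
def quenched_r3_grid():
    """A fixed connected disordered grid used by several oracle tests."""
    grid, _ = sample_connected_grid(ObstaclesParams(3, 0.3, 50.0), seed=7)
    return grid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_open_grid():
    return build_grid(2, 0.0, 0)
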