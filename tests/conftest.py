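import numpy as np
import pytest

import hgocean as h
from hgocean.grid import Grid


@pytest.fixture(scope="session")
def grid():
    return Grid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast integration tests (100/1000 m edges kept sharp)."""
    return Grid(lat_edges=(-90.0, -54.0, -18.0, 18.0, 54.0, 90.0),
                depth_edges=(0.0, 50.0, 100.0, 300.0, 1000.0, 2500.0))


@pytest.fixture(scope="session")
def params():
    return h.ModelParams()


@pytest.fixture(scope="session")
def forcings(grid):
    return {epoch: h.generate_forcing(epoch, grid, seed=0)
            for epoch in ("present", "future", "future_physics")}


@pytest.fixture(scope="session")
def small_forcings(small_grid):
    return {epoch: h.generate_forcing(epoch, small_grid, seed=0)
            for epoch in ("present", "future", "future_physics")}


@pytest.fixture(scope="session")
def suite():
    """The full scenario suite at default resolution (shared across tests)."""
    return h.run_suite(seed=0)


def rng(seed=0):
    return np.random.default_rng(seed)
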