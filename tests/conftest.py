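import numpy as np
import pytest

from infolength import GaussianState, Grid1D, gaussian_to_grid
from infolength.processes import ProcessSpec


@pytest.fixture(scope="session")
def unit_grid() -> Grid1D:
    """Grid wide enough for unit-variance Gaussians centered in [-2, 2]."""
    return Grid1D(-12.0, 12.0, 2048)


@pytest.fixture(scope="session")
def default_spec() -> ProcessSpec:
    """The default O-U relaxation configuration (gamma=1, D=0.5)."""
    return ProcessSpec(gamma=1.0, D=0.5, v=0.0)


@pytest.fixture(scope="session")
def default_init() -> GaussianState:
    return GaussianState(5.0, 0.3)


@pytest.fixture(scope="session")
def default_grid() -> Grid1D:
    return Grid1D(-10.0, 15.0, 2048)


def gauss(y: float, var: float, grid: Grid1D):
    """Grid Gaussian by mean/variance (test helper)."""
    return gaussian_to_grid(GaussianState(y, 1.0 / (2.0 * var)), grid)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
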