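import numpy as np
import pytest

from chaosmorph import rd_core as rc
from chaosmorph import segment_dynamics as sd


@pytest.fixture
def small_grid():
    return rc.SpatialGrid(nx=32, ny=9, Lx=1.0, Ly=1.0)


@pytest.fixture
def strip_grid():
    """Wide periodic strip used by the decay / dispersion examples."""
    return rc.SpatialGrid(nx=128, ny=3, Lx=2 * np.pi, Ly=1.0)


@pytest.fixture
def segment_grid():
    return rc.SpatialGrid(nx=256, ny=5, Lx=1.0, Ly=1.0)


@pytest.fixture
def three_segment_basis(segment_grid):
    return sd.build_segment_basis([0.25, 0.5, 0.75], 0.02, segment_grid)


@pytest.fixture
def rossler_system():
    return sd.AmplitudeSystem(n_vars=3, vfield=sd.rossler_vfield())


def fourier_amplitude(profile: np.ndarray, x: np.ndarray, k: float) -> complex:
    """Projection of a periodic 1-D profile onto exp(i k x)."""
    return np.sum(profile * np.exp(-1j * k * x)) * 2.0 / len(x)
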