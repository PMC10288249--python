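import numpy as np
import pytest

from elastopinn.fields import ElasticityField
from elastopinn.grid import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return GridSpec(q=8, h=0.5, t=1.0)


def smooth_disc_field(grid: GridSpec, nu: float = 0.5, width: float = 0.6):
    """Smooth stiff inclusion: E rises from 0.1 to 1.0 MPa across a
    tanh-smoothed disc boundary (smoothness keeps the discrete
    equilibrium residual small at the truth)."""
    x, y = grid.coordinates()
    c = grid.extent / 2
    r = np.hypot(x - c, y - c)
    E = 0.1 + 0.9 * 0.5 * (1.0 - np.tanh((r - 0.25 * grid.extent) / width))
    return ElasticityField(E=E, nu=np.full_like(E, nu))


@pytest.fixture
def desk_grid():
    """The standard reduced-scale grid used by training experiments."""
    return GridSpec(q=32, h=10.0 / 31, t=1.0)
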