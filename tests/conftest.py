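import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from pengdisp.env import EnvLayer, EnvStack, standardize
from pengdisp.grid import GridSpec, make_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_grid() -> GridSpec:
    """A 20x20 lattice over a 10x10 degree box."""
    return make_grid((-70.0, -60.0, -60.0, -50.0), cell_deg=0.5)


@pytest.fixture
def coarse_study_grid() -> GridSpec:
    """The study bounds at a desk-scale 0.5-degree resolution (70x200)."""
    return make_grid(cell_deg=0.5)


@pytest.fixture
def random_stack(small_grid) -> EnvStack:
    """Two independent white-noise layers on the small grid, standardized."""
    rng = np.random.default_rng(7)
    stack = EnvStack(small_grid)
    stack.add(EnvLayer("BAT", rng.uniform(0, 100, small_grid.shape)))
    stack.add(EnvLayer("SST", rng.uniform(0, 10, small_grid.shape)))
    return standardize(stack)
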