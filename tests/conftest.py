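import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dielshift import DielMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

GRID_2H = tuple(float(h) for h in range(0, 24, 2))
GRID_4H = tuple(float(h) for h in range(0, 24, 4))


@pytest.fixture
def grid_2h():
    return GRID_2H


@pytest.fixture
def grid_4h():
    return GRID_4H


@pytest.fixture
def small_matrix(grid_2h):
    """Three genes on the 2-h grid: flat, dusk-peaked, dawn-peaked."""
    t = np.asarray(grid_2h)
    rows = np.vstack(
        [
            np.full(12, 5.0),
            1.0 + 3.0 * (1.0 + np.cos(2 * np.pi * (t - 12.0) / 24.0)) / 2.0,
            1.0 + 3.0 * (1.0 + np.cos(2 * np.pi * t / 24.0)) / 2.0,
        ]
    )
    return DielMatrix("testspecies", grid_2h, ("flat", "duskish", "dawnish"), rows)
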