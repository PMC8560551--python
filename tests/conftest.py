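import numpy as np
import pytest

from macrocup.params import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def coarse_params():
    """Full-size cell (R0 = 10 um) on the coarse production mesh."""
    return SimulationParams(dx=0.2, seed=1)


@pytest.fixture
def small_params():
    """Small cell on a small grid for cheap mechanics checks."""
    return SimulationParams(R0=5.0, dx=0.2, Lr=10.0, Lz=20.0, box=16.0,
                            seed=1)
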