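import numpy as np
import pytest

from circumkin import (
    CircumnutationParams,
    default_stereo_rig,
    simulate_trajectory,
)


@pytest.fixture
def circle_params():
    """Noise-free planar circle: radius 10 mm, period 90 min, 3-min frames."""
    return CircumnutationParams(
        period=90.0, amplitude_major=10.0, amplitude_minor=10.0, n_cycles=3, dt=3.0
    )


@pytest.fixture
def helix_params():
    """Noise-free 5-turn helix with elliptical cross-section."""
    return CircumnutationParams(
        period=90.0,
        amplitude_major=12.0,
        amplitude_minor=5.0,
        growth_rate=0.5,
        n_cycles=5,
        dt=3.0,
    )


@pytest.fixture
def helix(helix_params):
    return simulate_trajectory(helix_params, seed=11)


@pytest.fixture
def rig():
    return default_stereo_rig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
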