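import numpy as np
import pytest

from tightropekit import SimulationConfig


@pytest.fixture
def cfg():
    """Default imaging configuration (12.5 fps, 300 s, 0.04 um noise)."""
    return SimulationConfig()


@pytest.fixture
def quiet_cfg():
    """Noise-free configuration for exact round-trip checks."""
    return SimulationConfig(localization_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
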