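import numpy as np
import pytest

from origamikin import CameraConfig, OpticsConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def optics():
    return OpticsConfig()


@pytest.fixture
def camera():
    return CameraConfig()


@pytest.fixture
def quiet_camera():
    """Noise parameters at zero so rendered frames equal their expectation."""
    return CameraConfig(read_noise_sd=0.0)
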