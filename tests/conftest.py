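import numpy as np
import pytest

from vertiforce import CantileverModel, DetectionModel


@pytest.fixture
def reference_model() -> CantileverModel:
    """The instrument's operating point: 5.19e-6 N/m, tau=0.125 ms, 295 K."""
    return CantileverModel(stiffness=5.19e-6, correlation_time=0.125e-3,
                           temperature=295.0)


@pytest.fixture
def quiet_detection() -> DetectionModel:
    return DetectionModel(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
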