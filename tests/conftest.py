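import numpy as np
import pytest

from antkin import synth


@pytest.fixture
def default_bee():
    return synth.make_bee_profile()


@pytest.fixture
def quiet_bee():
    """Noise-free deterministic profile."""
    return synth.make_bee_profile({"noise_sd": 0.0, "onset_jump": 0.0})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
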