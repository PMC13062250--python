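import numpy as np
import pytest

from ssvepauth.simulate import ChannelMontage, SimConfig


@pytest.fixture
def oz_montage() -> ChannelMontage:
    return ChannelMontage(("Oz",), (1.0,), (1.0,))


@pytest.fixture
def three_channel_montage() -> ChannelMontage:
    return ChannelMontage()


@pytest.fixture
def clean_cfg() -> SimConfig:
    """No background at all: the pure evoked component (amplitude 1)."""
    return SimConfig(noise_scale=0.0, alpha_amp=0.0, line_amp=0.0)


@pytest.fixture
def pink_only_cfg() -> SimConfig:
    """Broadband 1/f background without alpha or line components."""
    return SimConfig(alpha_amp=0.0, line_amp=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
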