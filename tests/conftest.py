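import numpy as np
import pytest

from noiseschema.frontend import FrontendConfig, Waveform, design_filterbank


@pytest.fixture(scope="session")
def small_frontend() -> FrontendConfig:
    """Light front end for unit tests: few kernels, fast to apply."""
    return FrontendConfig(rates=(2,), scales=(1.0,), channel_stride=30)


@pytest.fixture(scope="session")
def filterbank():
    return design_filterbank(30, 20.0, 10_000.0, 20_000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tone(freq, duration=0.5, sr=20_000.0, amp=0.1):
    t = np.arange(int(duration * sr)) / sr
    return Waveform(amp * np.sin(2 * np.pi * freq * t), sr)
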