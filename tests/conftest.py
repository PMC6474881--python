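import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20190419)


@pytest.fixture(scope="session")
def pink_noise_10min():
    """One 10-minute pink-noise record at 256 Hz (the standard validation size)."""
    from stationary_dfa import colored_noise

    fs = 256.0
    return colored_noise(1.0, int(600 * fs), fs=fs, seed=7), fs
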