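import numpy as np
import pytest

from notchkit import make_probe


@pytest.fixture(scope="session")
def short_probe():
    """8 s seeded flat-noise probe, enough for stable Welch averages."""
    return make_probe("flat_noise", duration_s=8.0, rate=44100, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
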