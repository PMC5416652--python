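import numpy as np
import pytest

from tonguelab import GeneratorParams, make_corpus

SMALL = GeneratorParams(height=96, width=96)


@pytest.fixture(scope="session")
def small_params():
    """Compact generator settings used by most tests (faster clustering;
    colour structure identical to the defaults)."""
    return SMALL


@pytest.fixture(scope="session")
def small_corpus(small_params):
    """45-image balanced corpus shared across pipeline tests."""
    return make_corpus(45, small_params, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
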