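import numpy as np
import pytest

from motiongrade.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """A small but geometrically valid phantom for fast tests."""
    return generate_phantom(PhantomConfig(shape=(16, 24, 24), seed=7))


@pytest.fixture
def tiny_config():
    """Smallest phantom config the network geometry accepts (depth >= 14)."""
    return PhantomConfig(shape=(14, 14, 14), seed=3)
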