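import numpy as np
import pytest

from ndnseg.synthdata import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom():
    """One deterministic 64x64x32 phantom (volume, labels)."""
    return generate_phantom(PhantomConfig(), rng=np.random.default_rng(7))


@pytest.fixture
def small_phantom():
    """A small 32x32x16 phantom for fast geometric tests."""
    config = PhantomConfig(
        shape=(32, 32, 16),
        whole_semi_axes=(8, 8, 5),
        core_semi_axes=(5, 5, 3),
        enhancing_semi_axes=(2, 2, 1.5),
        brain_semi_axes=(14, 14, 7),
        center_jitter=(2, 2, 1),
    )
    return generate_phantom(config, rng=np.random.default_rng(11))
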