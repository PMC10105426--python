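import numpy as np
import pytest

from thyroseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 64x64 phantom sample."""
    return generate_phantom(PhantomConfig(side=64, seed=5))


@pytest.fixture(scope="session")
def phantom_batch():
    """Eight deterministic 64x64 phantoms."""
    cfg = PhantomConfig(side=64, seed=0)
    return [generate_phantom(cfg, seed=10 + i) for i in range(8)]
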