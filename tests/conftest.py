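import numpy as np
import pytest

from vesselseg.synthetic_phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 128x128 phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(height=128, width=128, seed=7))


@pytest.fixture(scope="session")
def default_phantom():
    """One default-size (256x256) phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
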