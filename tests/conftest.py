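import numpy as np
import pytest

from tomoenhance.phantom import generate_phantom
from tomoenhance.projections import forward_project


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 sphere-in-cube phantom used by projection/reconstruction tests."""
    return generate_phantom(64, 6, 6, 14, seed=7)


@pytest.fixture(scope="session")
def small_projections(small_phantom):
    return forward_project(small_phantom, np.linspace(0.0, 180.0, 91))


@pytest.fixture(scope="session")
def random_image(rng):
    return rng.random((48, 48)).astype(np.float32) * 3.0 + 1.0
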