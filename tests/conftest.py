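import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_gray(rng):
    """A random float image on the canonical 0-255 scale."""
    return rng.uniform(0.0, 255.0, size=(48, 64))
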