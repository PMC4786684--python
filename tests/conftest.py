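import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160307)


@pytest.fixture
def random_mask_pair(rng):
    """A factory for random small binary mask pairs."""

    def _make(shape=(16, 16), p=0.4):
        return rng.random(shape) < p, rng.random(shape) < p

    return _make
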