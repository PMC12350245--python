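import numpy as np
import pytest

from specseg.phantoms import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, fast phantom family used across unit tests."""
    return PhantomConfig(height=16, width=16, n_bands=4,
                         lesion_radius_range=(2.0, 3.0),
                         signature_centers=(1.0, 2.5), seed=11)
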