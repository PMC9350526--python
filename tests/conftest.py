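import numpy as np
import pytest

from cmbcascade import phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_pairs():
    """A handful of default phantoms, normalized, for integration tests."""
    cfg = phantom.PhantomConfig(seed=3)
    return [(phantom.min_max_normalize(i), m)
            for i, m in phantom.generate_dataset(cfg, 6)]


@pytest.fixture()
def random_mask_pairs(rng):
    """1,000 random binary mask pairs on a small grid."""
    shape = (12, 10)
    return [((rng.random(shape) > 0.6).astype(np.uint8),
             (rng.random(shape) > 0.6).astype(np.uint8)) for _ in range(1000)]
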