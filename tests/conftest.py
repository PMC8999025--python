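import numpy as np
import pytest

from nirsconn import load_default_montage
from nirsconn.synthetic import NoiseSpec, make_block_correlation


@pytest.fixture(scope="session")
def montage():
    return load_default_montage()


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseSpec.quiet()


@pytest.fixture(scope="session")
def modular_truth():
    """ROI-block correlation target used throughout (within 0.8, between 0.3)."""
    return make_block_correlation(0.8, 0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
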