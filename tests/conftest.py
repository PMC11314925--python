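import numpy as np
import pytest

from sonoforce import default_phantom, generate_trial_dataset
from sonoforce.chirp import ChirpConfig


@pytest.fixture(scope="session")
def phantom():
    return default_phantom(speckle_contrast=0.5, snr_db=30.0, seed=0)


@pytest.fixture(scope="session")
def dataset(phantom):
    """Default three-trial synthetic dataset (trials 1-2 train, 3 test)."""
    return generate_trial_dataset(phantom, seed=0)


@pytest.fixture(scope="session")
def chirp_config():
    return ChirpConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
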