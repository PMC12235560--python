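import numpy as np
import pytest

from motionbag import SimConfig, generate_motion_cohort, generate_training_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured simulation for fast unit tests."""
    return SimConfig(n_train=120, n_test_subjects=60, n_features=40, n_latent=6, seed=11)


@pytest.fixture(scope="session")
def train_cohort(small_config):
    return generate_training_cohort(small_config)


@pytest.fixture(scope="session")
def motion_cohort(small_config):
    return generate_motion_cohort(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
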