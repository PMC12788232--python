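import numpy as np
import pytest

from kicksyn.preprocess import PreprocessConfig
from kicksyn.synthgen import (GeneratorConfig, generate_ground_truth,
                              generate_study)


@pytest.fixture(scope="session")
def ground_truth():
    """Canonical 15-muscle, 3-synergy ground truth used across modules."""
    return generate_ground_truth(15, 3, seed=1)


@pytest.fixture(scope="session")
def fast_config():
    """Down-scaled study configuration for end-to-end tests."""
    return GeneratorConfig(n_subjects=4, n_trials=2, noise_sd=0.02,
                           trial_duration_s=1.0, sampling_rate=1000.0,
                           seed=11)


@pytest.fixture(scope="session")
def fast_preprocess():
    return PreprocessConfig(sampling_rate=1000.0)


@pytest.fixture(scope="session")
def small_study(fast_config):
    return generate_study(fast_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
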