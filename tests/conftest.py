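import numpy as np
import pytest

from thermocomplexity.features import extract_feature_table
from thermocomplexity.synthetic import (
    SyntheticCohortConfig,
    default_profiles,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_config():
    """Short cohort settings used across tests: ~7 h recordings (2560
    samples) keep the dyadic decomposition valid while staying fast."""
    return SyntheticCohortConfig(
        n_per_group=3, duration_s=25600.0, fs_hz=0.1, seed=42, artifact_rate=0.5
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(default_profiles(), small_config)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    return extract_feature_table(small_cohort, include_mse=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
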