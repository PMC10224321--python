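import numpy as np
import pytest

from fitrank.preprocessing import build_labeled_dataset, clean_table, frequency_filter
from fitrank.synthetic_data import (
    AffibodySimConfig,
    simulate_affibody_library,
    simulate_enrichment_reads,
)


@pytest.fixture(scope="session")
def small_config() -> AffibodySimConfig:
    return AffibodySimConfig(n_unique=300, prevalence=0.08, seed=11)


@pytest.fixture(scope="session")
def small_library(small_config):
    return simulate_affibody_library(small_config)


@pytest.fixture(scope="session")
def small_reads(small_library, small_config):
    dataset, _ = small_library
    return simulate_enrichment_reads(dataset, small_config)


@pytest.fixture(scope="session")
def small_labeled(small_reads):
    naive, macs, facs = small_reads
    return build_labeled_dataset(
        set(clean_table(naive)[0].counts),
        frequency_filter(clean_table(macs)[0]),
        frequency_filter(clean_table(facs)[0]),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
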