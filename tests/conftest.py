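import numpy as np
import pytest

from connhc import SimulationConfig, simulate_cohort
from connhc.connectome import NetworkPartition


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort: 10 networks, planted
    effect, reused read-only across tests."""
    config = SimulationConfig(
        n_group1=12,
        n_group2=12,
        n_parcels=30,
        network_sizes=[3] * 10,
        n_timepoints=120,
        seed=42,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_partition(small_cohort):
    return NetworkPartition.from_atlas(small_cohort.atlas)
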