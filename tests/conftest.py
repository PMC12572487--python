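import numpy as np
import pytest

from mhnet.synthetic_data import SimConfig, generate_cohort, generate_signal_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_sim_config(**overrides) -> SimConfig:
    """Small cohort for fast structural tests: 2 networks x 2 clusters x
    2 regions x 4 voxels, 60 time points, 10 subjects per class."""
    base = dict(
        n_subjects_per_class=10,
        n_networks=2,
        clusters_per_network=2,
        regions_per_cluster=2,
        voxels_per_region=4,
        n_time=60,
        effect=[(("net1", "net2"), 0.4)],
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    cohort, hierarchy = generate_cohort(tiny_sim_config(), gamma=0.05)
    return cohort, hierarchy


@pytest.fixture(scope="session")
def tiny_signals():
    config = tiny_sim_config()
    subjects, labels, phenotypes = generate_signal_cohort(config)
    return config, subjects, labels, phenotypes
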