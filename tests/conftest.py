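import numpy as np
import pytest

from boldsense import synthetic as syn
from boldsense.grid import VolumeGrid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231108)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete cohort configuration."""
    return syn.CohortConfig(n_young=3, n_old=3, grid_shape=(8, 8, 6), seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return syn.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def noiseless_cohort(tiny_config):
    return syn.generate_cohort(tiny_config.noiseless())


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid((6, 6, 5), (2.2, 2.2, 2.0))
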