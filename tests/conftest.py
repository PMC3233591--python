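import numpy as np
import pytest

from twinglyc.simulate import SimulationConfig, generate_cohort
from twinglyc.phenotypes import add_phenotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_mz_pairs=300, n_dz_pairs=200, seed=1234)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def derived_cohort(small_cohort):
    return add_phenotypes(small_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
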