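import numpy as np
import pytest

from ctnetwb import SimulationConfig, default_parcel_table, simulate_cohort

SMALL_PARCELS = [
    ("LH_A_One", 80),
    ("RH_A_Two", 90),
    ("LH_B_Three", 70),
    ("RH_B_Four", 110),
    ("LH_C_Five", 60),
    ("RH_C_Six", 100),
    ("LH_D_Seven", 75),
    ("RH_D_Eight", 95),
]


@pytest.fixture(scope="session")
def parcel_table():
    return default_parcel_table()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=10, parcel_spec=list(SMALL_PARCELS), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One 65-subject null cohort at the bundled 32-parcel layout."""
    return simulate_cohort(SimulationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
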