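import numpy as np
import pytest

from conngrad.simulate import SimulationParams, place_parcels, simulate_cohort


@pytest.fixture(scope="session")
def small_params():
    """Cohort conditions small enough for per-test use."""
    return SimulationParams(
        n_regions=60,
        n_subjects_per_group=10,
        n_genes=100,
        n_signal_genes=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def region_table():
    return place_parcels(n_regions=60, n_networks=7, seed=1, n_subcortical=16)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
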