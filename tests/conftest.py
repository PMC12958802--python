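import numpy as np
import pytest

from gpkern.simulate import (
    SimConfig,
    derive_hybrid_genotypes,
    make_testcross_design,
    simulate_environments,
    simulate_inbred_panel,
    simulate_phenotypes,
    split_train_test,
)

BALANCED = {
    "additive": 0.3,
    "dominance": 0.1,
    "epistatic": 0.1,
    "gxe": 0.1,
    "environment": 0.2,
    "residual": 0.2,
}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_inbreds=33,
        n_testers=3,
        n_snps=120,
        n_sites=4,
        n_years=2,
        variance_fractions=BALANCED,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_inbred_panel(small_config)


@pytest.fixture(scope="session")
def small_design():
    return make_testcross_design(3, 30, 2, seed=5)


@pytest.fixture(scope="session")
def small_hybrids(small_panel, small_design):
    return derive_hybrid_genotypes(small_panel, small_design)


@pytest.fixture(scope="session")
def small_trial(small_config):
    return simulate_environments(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_hybrids, small_trial, small_config):
    return simulate_phenotypes(small_hybrids, small_trial, small_config)


@pytest.fixture(scope="session")
def split_table(small_phenotypes):
    return split_train_test(small_phenotypes, test_site_year_count=2, cap=50, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
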