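import numpy as np
import pytest

from isofeed.isotopes import derive_phenotypes
from isofeed.simulate import SimulationConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_families=4, n_fish_per_tank=12, n_snps=400, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    geno = simulate_genotypes(small_config)
    ind, tanks, truth = simulate_phenotypes(geno, small_config)
    return geno, ind, tanks, truth


@pytest.fixture(scope="session")
def derived_small(small_experiment):
    _geno, ind, tanks, _truth = small_experiment
    return derive_phenotypes(ind, tanks)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
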