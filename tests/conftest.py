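import numpy as np
import pytest

import cocoondyn as cd
from cocoondyn.mcmc import ChainConfig


@pytest.fixture(scope="session")
def small_truth():
    """A 3-site x 4-sample x 4-year design, quick enough for fitting tests."""
    base = cd.default_study_design()
    return cd.default_study_design(
        seed=2, n_sites=3, n_samples=4, n_years=4,
        p_theta=base.p_theta[:3], p_kappa=base.p_kappa[:3],
        N_mean=base.N_mean[:3])


@pytest.fixture(scope="session")
def small_sim(small_truth):
    return cd.simulate_dataset(small_truth)


@pytest.fixture(scope="session")
def small_counts(small_sim):
    return small_sim.counts


@pytest.fixture(scope="session")
def small_priors(small_counts):
    return cd.PriorSpec.from_counts(small_counts)


@pytest.fixture(scope="session")
def small_fit(small_counts):
    """A short but real fit of the small design (shared across tests)."""
    cfg = ChainConfig.desk(seed=9, n_iterations=4000, burn_in=2000, thin=10)
    return cd.run_chains(small_counts, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
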