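import numpy as np
import pytest

from merlcross import Scenario, simulate_crossover, treadmill_fixture


@pytest.fixture(scope="session")
def treadmill():
    return treadmill_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def simulated_trial():
    """A moderately censored exponential trial, fixed seed."""
    sc = Scenario(family="exponential", theta=1.4, rho_latent=0.7,
                  n_per_seq=24, censoring_target=0.3, seed=7)
    return simulate_crossover(sc)
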