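import numpy as np
import pytest

from seasonmix import SimulationParams, build_covariates, make_design, simulate_community


@pytest.fixture(scope="session")
def design():
    """The default crossed design: 3 sites x 12 months x 4 depth layers."""
    return make_design()


@pytest.fixture(scope="session")
def cov(design):
    return build_covariates(design)


@pytest.fixture(scope="session")
def small_community(design):
    """A 150-genus table from the default 3-component mixture, with truth."""
    params = SimulationParams(n_genera=150)
    counts, truth = simulate_community(design, params, seed=5)
    return counts, truth, params


@pytest.fixture()
def rng():
    return np.random.default_rng(20160703)
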