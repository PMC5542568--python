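import numpy as np
import pytest

import gad7irt as g

# Stated-world seeds: chosen once, shared by the large-sample fixtures.
DATA_SEED = 12345
FIT_SEED = 54321


@pytest.fixture(scope="session")
def gad7_params() -> g.GRMParameters:
    """The shipped 7-item parameter table (primary-care sample)."""
    return g.default_gad7_parameters()


@pytest.fixture(scope="session")
def toy3_params() -> g.GRMParameters:
    """A small 3-item model for exhaustive/hand-checkable computations."""
    return g.GRMParameters(
        discrimination=[1.5, 2.5, 0.8],
        thresholds=[[-1.0, 0.0, 1.5], [-0.5, 1.0, 2.5], [0.0, 1.0, 2.0]],
    )


@pytest.fixture(scope="session")
def big_sample(gad7_params):
    """Synthetic sample at the study's size: n=3404, ~3% missing cells."""
    config = g.SyntheticConfig(
        n_respondents=3404, model=gad7_params, missing_rate=0.03, seed=DATA_SEED
    )
    return g.simulate_responses(config)


@pytest.fixture(scope="session")
def big_fit(big_sample):
    """Full Bayesian fit of the big sample (5 chains, 6000 iterations)."""
    data, _, _ = big_sample
    return g.GradedResponseModel(data).fit(
        chains=5, iterations=6000, burn_in=2000, retained=1000, seed=FIT_SEED
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
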