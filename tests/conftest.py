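import numpy as np
import pytest

from hedoseek.inference import SamplerConfig, fit_hierarchical
from hedoseek.synthetic_cohort import CohortSpec, generate_exp1, generate_exp2

# shared small-scale sampler configuration for unit tests
QUICK = SamplerConfig(n_chains=2, n_warmup=250, n_draws=250, seed=9)


@pytest.fixture(scope="session")
def quick_config():
    return QUICK


@pytest.fixture(scope="session")
def exp1_cohort():
    spec = CohortSpec(n_participants=8, experiment=1, model="accpos", seed=101)
    return generate_exp1(spec)


@pytest.fixture(scope="session")
def exp1_posterior(exp1_cohort):
    dataset, _, _ = exp1_cohort
    return fit_hierarchical("accpos", dataset, QUICK)


@pytest.fixture(scope="session")
def exp2_cohort():
    spec = CohortSpec(n_participants=8, experiment=2, model="full", seed=102)
    return generate_exp2(spec)


@pytest.fixture(scope="session")
def exp2_posterior(exp2_cohort):
    dataset, _, _ = exp2_cohort
    return fit_hierarchical("full", dataset, QUICK)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
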