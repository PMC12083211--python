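import numpy as np
import pytest

from gshlm import (
    HLMSpec,
    SamplerConfig,
    make_scenario,
    generate_scenario_data,
)


@pytest.fixture(scope="session")
def study_spec() -> HLMSpec:
    """The simulation-study model: p=2 cluster covariates, one level-2 X,
    single C1:C2 interaction."""
    return make_scenario("correct").hlm_spec


@pytest.fixture(scope="session")
def small_masked_data():
    """One small-sample replicate (J=36, nj=4) with the study's MAR masks."""
    sc = make_scenario("correct", J=36, nj=4)
    rng = np.random.default_rng(1234)
    complete, masked, truth = generate_scenario_data(sc, rng)
    return complete, masked, truth


@pytest.fixture(scope="session")
def short_config():
    return SamplerConfig(n_burn=200, n_post=400, n_chains=1, seed=7)
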