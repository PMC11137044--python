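import numpy as np
import pytest

from empen.mcmc import MCMCConfig
from empen.phenology import PhenologyParams
from empen.synthetic import GeneratorSpec, pg_like_params, random_phenology_params

# re-exported for the test modules
random_valid_params = random_phenology_params


@pytest.fixture
def pg_params() -> PhenologyParams:
    return pg_like_params()


@pytest.fixture
def pg_spec() -> GeneratorSpec:
    return GeneratorSpec(seed=1)


@pytest.fixture
def quick_mcmc() -> MCMCConfig:
    """Short chains for smoke-level fits."""
    return MCMCConfig(n_walkers=32, n_burn=400, n_steps=120, n_start=500)
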