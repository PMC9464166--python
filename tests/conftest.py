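import numpy as np
import pytest
from hypothesis import settings

import eicopool as ep

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design():
    return ep.CohortDesign(seed=11)


@pytest.fixture(scope="session")
def null_cohort(default_design):
    """Default two-arm cohort under the global null (all rho = 0)."""
    return ep.simulate_cohort(default_design, effects=ep.null_effects())


@pytest.fixture(scope="session")
def showcase_cohort(default_design):
    """Default two-arm cohort under the showcase (signal-bearing) conditions."""
    return ep.simulate_cohort(default_design)


@pytest.fixture(scope="session")
def showcase_scores(showcase_cohort):
    return ep.score_cohort(showcase_cohort, list(ep.DEFAULT_GENES))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
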