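import pytest
from hypothesis import settings

import cgpecon as cg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def run_config() -> cg.RunConfig:
    return cg.load_run_config()


@pytest.fixture(scope="session")
def cohort(run_config):
    """Default expected-mode cohort (814 patients)."""
    return cg.generate_cohort(run_config.generator)


@pytest.fixture(scope="session")
def cost_model(run_config) -> cg.CostModel:
    return run_config.costs


@pytest.fixture(scope="session")
def probs(cohort) -> cg.PathwayProbabilities:
    return cg.estimate_probabilities(cohort)
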