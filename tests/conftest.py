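import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hipshape.synthetic import GeneratorConfig, make_template, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def male_template():
    return make_template("male")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant synthetic cohort under default study conditions."""
    cfg = GeneratorConfig(n_participants=60, seed=11)
    configs, table, truth = simulate_cohort(cfg)
    return cfg, configs, table, truth
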