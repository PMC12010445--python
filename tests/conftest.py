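import pytest
from hypothesis import HealthCheck, settings

from opmdeploy import (
    OutcomeModelParams,
    Polarity,
    ScenarioConfig,
    run_sweep,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: fixed seed for every stochastic fixture in the suite
FIXTURE_SEED = 20240101


@pytest.fixture
def worked_params():
    """The package's reference configuration: moderate covariate and
    treatment effects, no interaction, balanced groups."""
    return OutcomeModelParams(beta0=0.0, beta_x=1.0, beta_t=1.0, beta_xt=0.0, p_x=0.5)


@pytest.fixture
def worked_scenario(worked_params):
    """Reference scenario: historically everyone treated, Y=1 desirable."""
    return ScenarioConfig(
        params=worked_params, historical_policy=1, polarity=Polarity.DESIRABLE
    )


@pytest.fixture(scope="session")
def default_sweep():
    """The full default parameter sweep, shared across test modules."""
    return run_sweep()
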