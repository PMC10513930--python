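import pytest
from hypothesis import HealthCheck, settings

from lipidyn.pipeline import run_pipeline
from lipidyn.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, shared across the suite."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(study):
    """Extraction -> quantification -> filtering -> imputation products."""
    return run_pipeline(study, seed=1)
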