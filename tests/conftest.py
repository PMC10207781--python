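import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario_config():
    """The packaged default scenario configuration."""
    from waitline.config import default_config

    return default_config()


@pytest.fixture(scope="session")
def pipeline_result(scenario_config):
    """One full pipeline run, shared across read-only tests."""
    from waitline.pipeline import run_pipeline

    return run_pipeline(scenario_config, seed=7)
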