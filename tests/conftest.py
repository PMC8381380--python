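import pytest
from hypothesis import HealthCheck, settings

from nifquant.pipeline import RunConfig, run
from nifquant.simulate import ScenarioParams, design_standards, simulate_timecourse

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ScenarioParams:
    return ScenarioParams(seed=1)


@pytest.fixture(scope="session")
def truth(params):
    return simulate_timecourse(params)


@pytest.fixture(scope="session")
def bundle(truth):
    return design_standards(truth.proteome)


@pytest.fixture(scope="session")
def pipeline_results():
    """Default stochastic scenario (CV 5%, 3 replicates), full pipeline."""
    return run(RunConfig(seed=1), write_outputs=False)


@pytest.fixture(scope="session")
def noiseless_results():
    """Noise-free single-replicate scenario for identity checks."""
    cfg = RunConfig(
        seed=1,
        scenario_overrides={
            "noise_cv_area": 0.0,
            "noise_od_sd": 0.0,
            "noise_abs_sd": 0.0,
            "replicates": 1,
        },
    )
    return run(cfg, write_outputs=False)
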