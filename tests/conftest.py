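import pytest
from hypothesis import HealthCheck, settings

from methrestore.pipeline import RunConfig, run_analysis
from methrestore.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic dataset at generator defaults (seed 3)."""
    cfg = SimulationConfig(seed=3)
    tables, counts, models, truth, sheet = simulate_dataset(cfg)
    return {"cfg": cfg, "tables": tables, "counts": counts,
            "models": models, "truth": truth, "sheet": sheet}


@pytest.fixture(scope="session")
def pipeline_run(default_sim):
    """Full pipeline result on the default synthetic dataset."""
    result = run_analysis(
        default_sim["tables"], default_sim["counts"],
        default_sim["models"], default_sim["sheet"], RunConfig(seed=3))
    return {**default_sim, "result": result}
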