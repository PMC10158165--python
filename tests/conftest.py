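import hypothesis
import pytest

from hgtscout.pipeline import PipelineConfig, run_pipeline
from hgtscout.simulate import SimulationConfig, simulate_fixture

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_bundle():
    """The default simulated fixture (8 species, 200 OGs, 10 planted HGT
    events, 5 contaminant scaffolds, noise off, seed 1)."""
    return simulate_fixture(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    return run_pipeline(
        PipelineConfig(simulate=SimulationConfig(seed=1), log_level="WARNING")
    )
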