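import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regvar.fixtures import FixtureConfig, generate_fixture
from regvar.pipeline import PipelineConfig, run_pipeline

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Default synthetic input bundle with its planted-truth manifest."""
    d = tmp_path_factory.mktemp("bundle")
    truth = generate_fixture(FixtureConfig(seed=7), d)
    return d, truth


@pytest.fixture(scope="session")
def pipeline_run(fixture_bundle, tmp_path_factory):
    """Full pipeline artifacts computed once over the session bundle."""
    indir, truth = fixture_bundle
    out = tmp_path_factory.mktemp("artifacts")
    cfg = PipelineConfig(input_dir=str(indir), out_dir=str(out), seed=7)
    report = run_pipeline(cfg)
    return cfg, out, truth, report
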