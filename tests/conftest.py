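import pytest

from roadsafe import synthetic
from roadsafe.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def raw_bundle():
    """Uncalibrated China-like synthetic inputs (fixed seed)."""
    return synthetic.generate_inputs(seed=1)


@pytest.fixture(scope="session")
def calibrated_bundle(raw_bundle):
    """Inputs rescaled onto the printed national milestones."""
    return synthetic.calibrate_to_anchors(raw_bundle)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full 27-scenario run on calibrated synthetic inputs."""
    return run_pipeline(RunConfig(seed=1))
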