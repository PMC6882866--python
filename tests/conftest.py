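import numpy as np
import pytest

from slowwave.config import PipelineConfig
from slowwave.io import default_geometry
from slowwave.pipeline import run_single_session
from slowwave.synth import SynthConfig, generate_channel, generate_session


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def synth_channel():
    """One default 60 s synthetic channel with its ground truth."""
    cfg = SynthConfig(duration=60.0, seed=11)
    trace, truth = generate_channel(cfg, np.random.default_rng(11))
    return cfg, trace, truth


@pytest.fixture(scope="session")
def default_session(geometry):
    """Default 32-channel, 60 s synthetic session."""
    cfg = SynthConfig(duration=60.0, seed=42)
    rec, truth = generate_session(cfg, geometry, session_id="fixture")
    return cfg, rec, truth


@pytest.fixture(scope="session")
def analyzed_session(default_session, geometry, pipeline_config):
    _, rec, _ = default_session
    return run_single_session(rec, geometry, pipeline_config)
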