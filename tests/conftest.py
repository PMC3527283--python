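import numpy as np
import pytest

from breakscan import make_fixture
from breakscan.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def scaled_fixture():
    """The 60 kbp scaled-down fixture, shared across the suite."""
    return make_fixture(seed=7, scaled=True)


@pytest.fixture(scope="session")
def scaled_result(scaled_fixture):
    """Full six-phase pipeline result on the scaled fixture."""
    fx = scaled_fixture
    config = PipelineConfig.scaled_defaults(seed=7)
    return run_pipeline(
        fx.reference,
        list(fx.mutants.values()),
        fx.panel,
        config,
        decoys=[fx.decoy],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)
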