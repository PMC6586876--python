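import numpy as np
import pytest

from prepexec.pipeline import PipelineConfig, run_pipeline
from prepexec.synth import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_units=24, n_trials=150, seed=5)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def default_session():
    """One session at the generator's default study conditions."""
    cfg = GeneratorConfig(seed=3)
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def default_report(default_session):
    """Full pipeline run on the default session (shared across tests)."""
    _, session, _ = default_session
    config = PipelineConfig(n_bootstrap_ci=150, d_prep=3, d_move=3)
    return config, run_pipeline(session, config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
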