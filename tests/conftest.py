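import numpy as np
import pytest

from gcsr.config import PipelineConfig
from gcsr.synth import GcsrEffectSpec, generate_recording, theta_boost
from gcsr.task import ParticipantModel, SessionConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One default simulated session (30 go practice + 3 stop blocks)."""
    return simulate_session(ParticipantModel(), SessionConfig(), seed=11)


@pytest.fixture(scope="session")
def small_session():
    """A short session for fast pipeline tests (1 stop per class per block)."""
    cfg = SessionConfig(n_sets_per_block=3, trial_period_ms=1500)
    return simulate_session(ParticipantModel(), cfg, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_session):
    return generate_recording(small_session.trials, GcsrEffectSpec(), seed=8)


@pytest.fixture
def quiet_spec():
    """Background-only effect spec (no bursts, no blinks)."""
    return GcsrEffectSpec(amplitude_by_condition={}, blink_rate_hz=0.0)


@pytest.fixture
def pipeline_config():
    return PipelineConfig()
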