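import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from credassign import AdaptationState, LearningParams
from credassign.paradigms import Schedule, probe_block, shifted_schedules


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mrl_params():
    return LearningParams(hypothesis="MRL")


@pytest.fixture
def prl_params():
    return LearningParams(hypothesis="PRL")


@pytest.fixture
def zero_state():
    return AdaptationState.zeros()


@pytest.fixture(scope="session")
def stt_schedule():
    """Single-target schedule (75 baseline + 125 training, probes at 90)."""
    stt, _, _ = shifted_schedules(smoothed_errors=np.zeros(125), seed=7)
    return stt


@pytest.fixture(scope="session")
def recovery_schedule(stt_schedule):
    """STT schedule plus a multi-direction generalization probe block."""
    block = probe_block(
        np.arange(30.0, 151.0, 15.0), repeats=3, reference_viscosity=22.5, seed=11
    )
    return Schedule(
        entries=stt_schedule.entries + block,
        metadata={**stt_schedule.metadata, "probe_block": True},
    )
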