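import numpy as np
import pytest

from tremorgain.config import RunConfig
from tremorgain.protocol import TrialSpec
from tremorgain.synth import CohortEffects, VirtualParticipant, draw_participant


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def patient() -> VirtualParticipant:
    """One deterministic patient drawn from the default effect structure."""
    rng = np.random.default_rng(42)
    return draw_participant("pET01", "pET", CohortEffects.default().pet, rng)


@pytest.fixture()
def quiet_participant() -> VirtualParticipant:
    """Noise-free patient: pure tremor sinusoid, no drift, no blinks."""
    return VirtualParticipant(
        pid="q1",
        group="pET",
        maxf=60.0,
        tremor_freq_hz=6.0,
        tremor_amp0=0.02,
        gain_beta={"vo": 0.5, "va": 0.5, "ao": 0.5},
        drift_amp=0.0,
        noise_sd=0.0,
        pupil_noise_sd=0.0,
        blink_rate_hz=0.0,
        pupil_arousal_mm={(t, g): 0.0 for t in ("vo", "va", "ao") for g in ("low", "high")},
    )


@pytest.fixture()
def trial_low() -> TrialSpec:
    return TrialSpec(index=1, feedback_type="vo", gain_level="low")


@pytest.fixture()
def trial_high() -> TrialSpec:
    return TrialSpec(index=2, feedback_type="vo", gain_level="high")
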