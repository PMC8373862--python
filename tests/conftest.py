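import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from digitcoord import SimulationConfig, TrialRecording, analyze_trials, simulate_session
from digitcoord.trajio import DIGITS


def make_sine_trial(
    phase_offsets=(0.0, 0.2, 0.4, 0.6, 0.8),
    period=0.5,
    frame_rate=300.0,
    duration=8.0,
    noise_sd=0.0,
    seed=0,
    task="BRT",
    orth_ratio=0.3,
):
    """Five-digit sinusoidal trial with known phase offsets (y = extension)."""
    rng = np.random.default_rng(seed)
    n = int(round(frame_rate * duration))
    t = np.arange(n) / frame_rate
    x, y, conf = {}, {}, {}
    for i, d in enumerate(DIGITS):
        theta = 2 * np.pi * (t / period + phase_offsets[i])
        y[d] = np.sin(theta) + rng.normal(0, noise_sd, n)
        x[d] = orth_ratio * np.cos(theta) + rng.normal(0, noise_sd, n)
        conf[d] = np.ones(n)
    return TrialRecording(
        participant_id="p1", day=1, block=1, trial_index=1, task=task,
        frame_rate=frame_rate, duration=duration, x=x, y=y, confidence=conf,
    )


@pytest.fixture(scope="session")
def small_session():
    """A small but protocol-complete simulated cohort (3 participants, 2 days)."""
    return simulate_session(SimulationConfig(n_participants=3, days=(1, 8), seed=42))


@pytest.fixture(scope="session")
def small_session_result(small_session):
    return analyze_trials(small_session.trials)
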