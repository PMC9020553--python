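import numpy as np
import pytest

import gazeorient as go


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_params():
    """A deterministic participant: no noise, no dropout, always shifts."""
    return go.ParticipantParams(
        participant="clean", group="TD",
        p_shift_to_eyes=1.0, p_shift_from_eyes=1.0,
        noise_sd=0.0, dropout=0.0)


@pytest.fixture
def default_params():
    return go.ParticipantParams()


def saccade_recording(amplitude, rate, phase=0.0, pre=0.5, post=0.5,
                      velocity_scale=1.0, noise_sd=0.0, seed=0):
    """A noiseless (or noisy) recording with one raised-cosine saccade.

    Returns (recording, true_onset, duration, true_peak_velocity).
    """
    duration = go.main_sequence_duration(amplitude,
                                         velocity_scale=velocity_scale)
    dt = 1.0 / rate
    n = int((pre + duration + post) * rate) + 1
    t = np.arange(n) * dt
    onset = pre + phase * dt
    s = np.clip((t - onset) / duration, 0.0, 1.0)
    x = amplitude * go.raised_cosine_displacement(s)
    y = np.zeros_like(x)
    if noise_sd > 0:
        r = np.random.default_rng(seed)
        x = x + r.normal(0, noise_sd, n)
        y = y + r.normal(0, noise_sd, n)
    rec = go.GazeRecording(t, x, y, np.ones(n, dtype=bool), rate)
    return rec, onset, duration, 2.0 * amplitude / duration
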