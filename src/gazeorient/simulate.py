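"""Synthetic gaze generator with exact ground truth.

Emulates a cued free-viewing paradigm: each trial shows a fixation cross for
1 s, then a face for 1.5 s positioned so gaze starts inside either the eye
region (eyes-cued) or the mouth region (mouth-cued).  A session has 60
trials, 30 per condition, with 10 actor identities and three emotions
(angry/happy/neutral) fully balanced.  With a participant-specific
probability, one saccade is made from the cued region to the other region at
a latency drawn from a shifted log-normal.

Saccades follow a raised-cosine velocity profile,

    v(t) = (V_p / 2) * (1 - cos(2 pi t / D)),   0 <= t <= D,

whose peak velocity is exactly V_p = 2 A / D for amplitude A and duration D;
this closed form is the oracle every downstream stage is tested against.
Durations follow a linear main sequence D = D0 + k * A.  Tonic hypo-arousal
is modelled as a multiplicative scaling of peak velocity at fixed amplitude,
implemented by inflating D by the reciprocal of the scale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_gaze import AOISet, GazeRecording, Rect

PRE_STIMULUS_S = 1.0     # fixation-cross epoch
STIMULUS_S = 1.5         # face epoch
TRIAL_S = PRE_STIMULUS_S + STIMULUS_S
N_TRIALS = 60
N_ACTORS = 10
EMOTIONS = ("angry", "happy", "neutral")
CONDITIONS = ("eyes_cued", "mouth_cued")

# Main-sequence defaults: D = D0 + k * A, giving peak velocities in the
# physiological 100-500 deg/s range for the 4-10 deg amplitudes used here.
MAIN_SEQUENCE_D0 = 0.021    # s
MAIN_SEQUENCE_SLOPE = 0.0022  # s per degree

# AOI layout fixtures (the stimuli are abstract rectangles, not face images):
# cued region centred on the fixation-cross position (the angular origin),
# the other region offset 5 deg vertically.  Eyes sit above the mouth
# (negative y is up in the screen convention).
AOI_SEPARATION_DEG = 5.0
EYES_SIZE = (8.0, 3.0)
MOUTH_SIZE = (6.0, 2.5)


def _rect_at(cx: float, cy: float, size: tuple[float, float]) -> Rect:
    w, h = size
    return Rect(cx - w / 2, cx + w / 2, cy - h / 2, cy + h / 2)


def aoi_layout(condition: str) -> AOISet:
    """AOI rectangles for one trial, cued region centred at the origin."""
    if condition == "eyes_cued":
        return AOISet(eyes=_rect_at(0.0, 0.0, EYES_SIZE),
                      mouth=_rect_at(0.0, AOI_SEPARATION_DEG, MOUTH_SIZE))
    if condition == "mouth_cued":
        return AOISet(eyes=_rect_at(0.0, -AOI_SEPARATION_DEG, EYES_SIZE),
                      mouth=_rect_at(0.0, 0.0, MOUTH_SIZE))
    raise ValueError(f"unknown condition: {condition}")


def main_sequence_duration(amplitude: float, d0: float = MAIN_SEQUENCE_D0,
                           slope: float = MAIN_SEQUENCE_SLOPE,
                           velocity_scale: float = 1.0) -> float:
    """Saccade duration from the linear main sequence.

    ``velocity_scale`` < 1 models hypo-arousal: D is inflated by 1/scale so
    that V_p = 2A/D is scaled down at fixed amplitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    return (d0 + slope * amplitude) / velocity_scale


@dataclass(frozen=True)
class SaccadeProfile:
    """One ground-truth saccade with raised-cosine kinematics."""

    onset: float          # s, on the session clock
    amplitude: float      # deg
    duration: float       # s
    direction: tuple[float, float]  # unit vector (dx, dy)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        norm = math.hypot(*self.direction)
        if self.amplitude > 0 and abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")

    @property
    def peak_velocity(self) -> float:
        """Closed form for the raised-cosine profile: V_p = 2A/D."""
        return 2.0 * self.amplitude / self.duration


def raised_cosine_displacement(s):
    """Fractional displacement at fractional time s in [0, 1].

    Integral of the raised-cosine velocity profile:
    x(s) = s - sin(2 pi s) / (2 pi), so x(0) = 0 and x(1) = 1.
    """
    s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
    return s - np.sin(2.0 * np.pi * s) / (2.0 * np.pi)


def simulate_saccade(amplitude: float, duration: float, rate: float,
                     direction: tuple[float, float] = (1.0, 0.0)):
    """Sample one raised-cosine saccade trajectory.

    Returns ``(t, dx, dy)``: times from saccade onset (inclusive of both
    endpoints) and displacement components.  Total displacement equals the
    amplitude exactly at t = D.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if rate not in (60, 120, 1200):
        raise ValueError(f"unsupported sampling rate: {rate}")
    n = int(math.floor(duration * rate)) + 1
    t = np.arange(n) / rate
    t = np.append(t, duration) if t[-1] < duration else t
    disp = amplitude * raised_cosine_displacement(t / duration)
    return t, disp * direction[0], disp * direction[1]


@dataclass(frozen=True)
class LatencyModel:
    """Shifted log-normal saccadic latency (seconds).

    ``median`` is the median of the log-normal part; total latency is
    ``shift + lognormal``.  Draws are redrawn above ``max_latency`` so the
    saccade always completes within the stimulus epoch.
    """

    median: float = 0.30
    sigma: float = 0.35
    shift: float = 0.10
    max_latency: float = 1.30

    def draw(self, rng: np.random.Generator) -> float:
        mu = math.log(self.median)
        for _ in range(100):
            lat = self.shift + rng.lognormal(mu, self.sigma)
            if lat <= self.max_latency:
                return lat
        return self.max_latency


@dataclass(frozen=True)
class ParticipantParams:
    """Generating parameters for one participant."""

    participant: str = "p00"
    group: str = "TD"
    #: probability that a mouth-cued trial produces a shift to the eyes
    p_shift_to_eyes: float = 0.75
    #: probability that an eyes-cued trial produces a shift away from the eyes
    p_shift_from_eyes: float = 0.40
    latency_to_eyes: LatencyModel = LatencyModel(median=0.28)
    latency_from_eyes: LatencyModel = LatencyModel(median=0.38)
    velocity_scale: float = 1.0
    noise_sd: float = 0.3          # deg, isotropic per sample
    dropout: float = 0.02          # per-sample invalidation probability
    blink_rate: float = 0.0        # blinks per second (contiguous gaps)
    blink_duration: float = 0.15   # s
    rate: float = 120.0

    def __post_init__(self) -> None:
        for p in (self.p_shift_to_eyes, self.p_shift_from_eyes, self.dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.velocity_scale <= 0:
            raise ValueError("velocity_scale must be positive")


def _session_plan(n_trials: int) -> list[tuple[str, int, str]]:
    """Balanced (condition, actor, emotion) plan.

    The base 60-trial block pairs every (actor, emotion) cell once per
    condition: 30/30 conditions, 20/20/20 emotions, 6 trials per actor.
    Longer sessions repeat the block; shorter ones truncate it.
    """
    base = [(cond, actor, emo)
            for actor in range(N_ACTORS)
            for emo in EMOTIONS
            for cond in CONDITIONS]
    reps = -(-n_trials // len(base))
    return (base * reps)[:n_trials]


def simulate_trial(condition: str, emotion: str, actor: int,
                   params: ParticipantParams, rng: np.random.Generator,
                   t_start: float = 0.0):
    """Simulate one trial; returns (t, x, y, valid, truth-dict).

    Gaze rests at the fixation cross (the origin) for 1 s, then inside the
    cued AOI for 1.5 s of stimulus.  With the condition's shift probability a
    single saccade is made to the centre of the other AOI.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition}")
    rate = params.rate
    n = int(round(TRIAL_S * rate))
    t_local = np.arange(n) / rate
    x = np.zeros(n)
    y = np.zeros(n)

    stim_onset = PRE_STIMULUS_S
    if condition == "eyes_cued":
        p_shift = params.p_shift_from_eyes
        lat_model = params.latency_from_eyes
        target = "mouth"
        direction = (0.0, 1.0)    # mouth is below the eyes
    else:
        p_shift = params.p_shift_to_eyes
        lat_model = params.latency_to_eyes
        target = "eyes"
        direction = (0.0, -1.0)

    shift = rng.random() < p_shift
    truth = {"condition": condition, "emotion": emotion, "actor": actor,
             "stim_onset": t_start + stim_onset, "shift_made": shift,
             "target": target if shift else "none",
             "latency": np.nan, "amplitude": np.nan, "duration": np.nan,
             "peak_velocity": np.nan}

    if shift:
        latency = lat_model.draw(rng)
        amplitude = AOI_SEPARATION_DEG
        duration = main_sequence_duration(
            amplitude, velocity_scale=params.velocity_scale)
        onset = stim_onset + latency
        s = np.clip((t_local - onset) / duration, 0.0, 1.0)
        disp = amplitude * raised_cosine_displacement(s)
        x += disp * direction[0]
        y += disp * direction[1]
        truth.update(latency=latency, amplitude=amplitude, duration=duration,
                     peak_velocity=2.0 * amplitude / duration)

    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
        y = y + rng.normal(0.0, params.noise_sd, n)

    valid = np.ones(n, dtype=bool)
    if params.dropout > 0:
        valid &= rng.random(n) >= params.dropout
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * TRIAL_S)
        for _ in range(n_blinks):
            b0 = rng.uniform(0.0, TRIAL_S - params.blink_duration)
            valid &= ~((t_local >= b0) & (t_local < b0 + params.blink_duration))
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return t_start + t_local, x, y, valid, truth


@dataclass
class Session:
    """One simulated participant session with ground truth."""

    participant: str
    group: str
    recording: GazeRecording
    trials: pd.DataFrame       # index, condition, emotion, actor, stim_onset
    truth: pd.DataFrame        # trial-level ground truth
    params: ParticipantParams


def simulate_session(params: ParticipantParams, rng: np.random.Generator,
                     n_trials: int = N_TRIALS) -> Session:
    """Simulate a full session (default 60 trials, 30 per condition)."""
    plan = _session_plan(n_trials)
    order = rng.permutation(len(plan))
    ts, xs, ys, vs, truths, trial_rows = [], [], [], [], [], []
    for i, j in enumerate(order):
        cond, actor, emo = plan[j]
        t, x, y, v, truth = simulate_trial(cond, emo, actor, params, rng,
                                           t_start=i * TRIAL_S)
        ts.append(t); xs.append(x); ys.append(y); vs.append(v)
        truth["trial"] = i
        truths.append(truth)
        trial_rows.append({"trial": i, "condition": cond, "emotion": emo,
                           "actor": actor, "stim_onset": truth["stim_onset"]})
    recording = GazeRecording(np.concatenate(ts), np.concatenate(xs),
                              np.concatenate(ys), np.concatenate(vs),
                              params.rate)
    trials = pd.DataFrame(trial_rows)
    truth_df = pd.DataFrame(truths)[
        ["trial", "condition", "emotion", "actor", "stim_onset", "shift_made",
         "target", "latency", "amplitude", "duration", "peak_velocity"]]
    return Session(params.participant, params.group, recording, trials,
                   truth_df, params)


@dataclass(frozen=True)
class GroupConfig:
    """Generating parameters for one group of participants."""

    name: str
    n: int
    p_shift_to_eyes: float = 0.75
    p_shift_from_eyes: float = 0.40
    latency_to_eyes_ms: float = 280.0
    latency_from_eyes_ms: float = 380.0
    latency_sd_ms: float = 60.0     # between-participant SD of the medians
    velocity_scale: float = 1.0
    velocity_scale_sd: float = 0.08  # between-participant SD of the scale
    p_shift_sd: float = 0.08         # between-participant SD of probabilities
    noise_sd: float = 0.3
    dropout: float = 0.02
    rate: float = 120.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for p in (self.p_shift_to_eyes, self.p_shift_from_eyes):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupConfig, ...]
    seed: int = 0
    n_trials: int = N_TRIALS


def _draw_participant(group: GroupConfig, idx: int,
                      rng: np.random.Generator) -> ParticipantParams:
    clip01 = lambda v: float(np.clip(v, 0.01, 0.99))
    lat_to = max(0.12, rng.normal(group.latency_to_eyes_ms,
                                  group.latency_sd_ms) / 1000.0)
    lat_from = max(0.12, rng.normal(group.latency_from_eyes_ms,
                                    group.latency_sd_ms) / 1000.0)
    scale = max(0.3, rng.normal(group.velocity_scale, group.velocity_scale_sd))
    return ParticipantParams(
        participant=f"{group.name}_{idx:03d}",
        group=group.name,
        p_shift_to_eyes=clip01(rng.normal(group.p_shift_to_eyes,
                                          group.p_shift_sd)),
        p_shift_from_eyes=clip01(rng.normal(group.p_shift_from_eyes,
                                            group.p_shift_sd)),
        latency_to_eyes=LatencyModel(median=lat_to),
        latency_from_eyes=LatencyModel(median=lat_from),
        velocity_scale=scale,
        noise_sd=group.noise_sd,
        dropout=group.dropout,
        rate=group.rate,
    )


def simulate_cohort(config: CohortConfig) -> list[Session]:
    """Simulate all sessions of a multi-group cohort, reproducibly.

    Each participant gets an independent child RNG spawned from the cohort
    seed, so sessions are independent and the whole cohort is a pure
    function of the config.
    """
    root = np.random.SeedSequence(config.seed)
    sessions: list[Session] = []
    n_total = sum(g.n for g in config.groups)
    children = root.spawn(n_total)
    k = 0
    for group in config.groups:
        for idx in range(group.n):
            rng = np.random.default_rng(children[k]); k += 1
            params = _draw_participant(group, idx, rng)
            sessions.append(simulate_session(params, rng,
                                             n_trials=config.n_trials))
    return sessions


def td_like_group(name: str = "TD", n: int = 20, **kw) -> GroupConfig:
    """A typically-developing-like group: eye bias and unscaled velocity."""
    return GroupConfig(name=name, n=n, **kw)


def ws_like_group(name: str = "WS", n: int = 20, **kw) -> GroupConfig:
    """A Williams-syndrome-like group: no eye bias (shift probabilities
    equal across conditions) and peak velocity scaled to 0.75x."""
    kw.setdefault("p_shift_to_eyes", 0.55)
    kw.setdefault("p_shift_from_eyes", 0.55)
    kw.setdefault("latency_to_eyes_ms", 380.0)
    kw.setdefault("latency_from_eyes_ms", 380.0)
    kw.setdefault("velocity_scale", 0.75)
    return GroupConfig(name=name, n=n, **kw)
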