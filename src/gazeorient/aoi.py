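"""Cued-AOI first-gaze-shift extraction and participant summaries.

The paradigm's primary outcomes are, per condition: (1) the proportion of
trials whose first gaze shift leaves the cued region for the other region
(eyes -> mouth or mouth -> eyes), and (2) the latency of that shift from
stimulus onset to saccade onset.  First saccades landing outside both
regions are rare by design and are excluded from both proportions and
latencies.  Participants contributing fewer than five valid trials to a
condition are excluded from that condition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_gaze import AOISet, GazeRecording
from .simulate import STIMULUS_S


def assign_aoi(x: float, y: float, aois: AOISet) -> str:
    """Label a point (degrees) as 'eyes', 'mouth', or 'outside'.

    Rectangle containment is boundary-inclusive.  The AOIs do not overlap,
    so the order of the tests is immaterial.
    """
    if aois.eyes.contains(x, y):
        return "eyes"
    if aois.mouth.contains(x, y):
        return "mouth"
    return "outside"


def _cued_aoi(condition: str) -> str:
    return "eyes" if condition == "eyes_cued" else "mouth"


def trial_validity(recording: GazeRecording, stim_onset: float,
                   condition: str, aois: AOISet,
                   min_valid_frac: float = 0.5,
                   stimulus_duration: float = STIMULUS_S) -> bool:
    """Is a trial usable?

    Valid iff gaze is inside the cued AOI at stimulus onset (nearest valid
    sample within one sampling interval of onset) AND at least
    ``min_valid_frac`` of the stimulus-epoch samples are valid.
    """
    epoch = recording.slice_time(stim_onset, stim_onset + stimulus_duration)
    if len(epoch) == 0:
        return False
    frac_valid = float(np.mean(epoch.valid))
    if frac_valid < min_valid_frac:
        return False
    near = np.abs(recording.t - stim_onset) <= 1.0 / recording.rate
    near &= recording.valid
    if not near.any():
        return False
    i = int(np.argmin(np.abs(recording.t[near] - stim_onset)))
    x0, y0 = recording.x[near][i], recording.y[near][i]
    return assign_aoi(float(x0), float(y0), aois) == _cued_aoi(condition)


@dataclass
class TrialShiftResult:
    """Outcome of the first-gaze-shift search for one trial.

    ``target`` is the landing AOI of the first saccade leaving the cued
    region: the non-cued AOI (a shift), ``'outside'`` (first shift missed
    both AOIs; trial excluded from proportions/latencies), or ``'none'``
    (gaze never left the cued region).  ``latency_any_ms`` is the latency to
    leave the cued region for anywhere; ``latency_ms`` is the latency of
    orienting into the non-cued AOI (equal to ``latency_any_ms`` except on
    'outside' trials, where a later AOI entry may define it for QC).
    """

    trial: int
    condition: str
    valid: bool
    shift_made: bool
    target: str            # 'eyes' | 'mouth' | 'outside' | 'none'
    latency_ms: float
    anticipatory: bool = False   # latency < 80 ms (flagged, retained)
    latency_any_ms: float = float("nan")


def first_gaze_shift(events, stim_onset: float, condition: str,
                     aois: AOISet, trial: int = -1,
                     window: float = STIMULUS_S,
                     anticipatory_ms: float = 80.0,
                     drop_anticipatory: bool = False) -> TrialShiftResult:
    """Find the first saccade leaving the cued AOI after stimulus onset.

    The qualifying saccade starts inside the cued AOI and lands outside it;
    its landing point (the saccade end position, i.e. the following
    fixation's start) is labelled with :func:`assign_aoi`.  Latency is
    anchored to saccade ONSET.  A landing outside both AOIs is recorded as
    ``target='outside'``; such trials are excluded from proportion and
    latency summaries downstream.  Anticipatory shifts (latency below 80 ms)
    are flagged and retained unless ``drop_anticipatory``.
    """
    cued = _cued_aoi(condition)
    noncued = "mouth" if cued == "eyes" else "eyes"
    saccades = []
    for e in sorted(events, key=lambda ev: ev.onset):
        if e.kind != "saccade" or not np.isfinite(e.start_x):
            continue
        lat = e.onset - stim_onset
        if 0 <= lat <= window:
            saccades.append((lat, e))

    leaving = None
    for lat, e in saccades:
        if assign_aoi(e.start_x, e.start_y, aois) != cued:
            continue
        landing = assign_aoi(e.end_x, e.end_y, aois)
        if landing == cued:
            continue
        if lat * 1000.0 < anticipatory_ms and drop_anticipatory:
            continue
        leaving = (lat, e, landing)
        break

    if leaving is None:
        return TrialShiftResult(trial=trial, condition=condition, valid=True,
                                shift_made=False, target="none",
                                latency_ms=float("nan"))
    lat, e, landing = leaving
    lat_ms = lat * 1000.0
    if landing == noncued:
        return TrialShiftResult(trial=trial, condition=condition, valid=True,
                                shift_made=True, target=landing,
                                latency_ms=lat_ms,
                                anticipatory=lat_ms < anticipatory_ms,
                                latency_any_ms=lat_ms)
    # first shift missed both AOIs; look for a later entry into the
    # non-cued AOI so the QC latency pair is still defined
    lat_to_aoi = float("nan")
    for lat2, e2 in saccades:
        if lat2 >= lat and assign_aoi(e2.end_x, e2.end_y, aois) == noncued:
            lat_to_aoi = lat2 * 1000.0
            break
    return TrialShiftResult(trial=trial, condition=condition, valid=True,
                            shift_made=False, target="outside",
                            latency_ms=lat_to_aoi,
                            anticipatory=lat_ms < anticipatory_ms,
                            latency_any_ms=lat_ms)


@dataclass
class ParticipantSummary:
    """Per participant x condition aggregates of the shift outcomes."""

    participant: str
    group: str
    condition: str
    n_valid: int
    prop_shift: float      # shifts to the non-cued AOI / analysable trials
    mean_latency_ms: float  # NaN when no shift occurred
    mean_ratio: float = float("nan")   # peak velocity / amplitude, 1/s
    included: bool = True  # False when n_valid < min_valid_trials


def summarize_participant(results: list[TrialShiftResult],
                          participant: str = "", group: str = "",
                          min_valid_trials: int = 5
                          ) -> list[ParticipantSummary]:
    """Aggregate trial shift results into per-condition summaries.

    Trials whose first shift landed outside both AOIs are excluded from the
    proportion's numerator and denominator and from latencies.  A condition
    with fewer than ``min_valid_trials`` valid trials is marked excluded.
    """
    out: list[ParticipantSummary] = []
    df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        return out
    for cond, grp in df.groupby("condition", sort=True):
        valid = grp[grp["valid"]]
        n_valid = int(len(valid))
        analysable = valid[valid["target"] != "outside"]
        shifted = analysable[analysable["shift_made"]]
        prop = float(len(shifted) / len(analysable)) if len(analysable) else float("nan")
        mean_lat = float(shifted["latency_ms"].mean()) if len(shifted) else float("nan")
        out.append(ParticipantSummary(
            participant=participant, group=group, condition=cond,
            n_valid=n_valid, prop_shift=prop, mean_latency_ms=mean_lat,
            included=n_valid >= min_valid_trials))
    return out


def summaries_frame(summaries: list[ParticipantSummary],
                    drop_excluded: bool = True) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in summaries])
    if drop_excluded and not df.empty:
        df = df[df["included"]].reset_index(drop=True)
    return df


def latency_agreement(results: list[TrialShiftResult]) -> float:
    """QC diagnostic: Pearson r between the latency to reach the non-cued
    AOI and the latency to leave the cued region for anywhere.

    Returns NaN (flagged undefined) with fewer than 3 paired latencies.
    In this paradigm first saccades rarely land outside both AOIs, so the
    two latencies nearly coincide and r should be close to 1.
    """
    to_aoi, to_any = [], []
    for r in results:
        if np.isfinite(r.latency_ms) and np.isfinite(r.latency_any_ms):
            to_aoi.append(r.latency_ms)
            to_any.append(r.latency_any_ms)
    if len(to_aoi) < 3:
        return float("nan")
    if np.std(to_aoi) == 0 or np.std(to_any) == 0:
        return 1.0 if np.allclose(to_aoi, to_any) else float("nan")
    return float(stats.pearsonr(to_aoi, to_any)[0])
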