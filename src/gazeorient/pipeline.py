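"""End-to-end orchestration: simulate -> detect -> shifts/arousal -> analyze.

Every stage is a pure function of (inputs, config, seed); a run writes its
events, summaries, model-comparison results and a manifest (config, package
version, seed) so that any result file can be regenerated exactly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aoi import (TrialShiftResult, first_gaze_shift, latency_agreement,
                  summaries_frame, summarize_participant, trial_validity)
from .ivt import IVTConfig, classify_ivt
from .mixedlm import (ComparisonResult, attach_bh, compare_models,
                      fit_random_intercept)
from .peak_velocity import (SamplingRateError, peak_velocity_ratio,
                            refine_peak_velocities, saccade_table)
from .simulate import (TRIAL_S, CohortConfig, Session, aoi_layout,
                       simulate_cohort)

log = logging.getLogger("gazeorient")


@dataclass
class RunConfig:
    """Pipeline settings; defaults are the paradigm's stated constants."""

    seed: int = 0
    out_dir: str | None = None
    ivt: IVTConfig = field(default_factory=IVTConfig.noise_robust)
    amplitude_min: float = 4.0       # deg, arousal-index inclusion
    min_valid_trials: int = 5        # per-condition participant inclusion
    min_valid_frac: float = 0.5      # per-trial sample-validity threshold
    alpha: float = 0.05
    fdr_q: float = 0.05
    cohort: CohortConfig | None = None


@dataclass
class SessionResult:
    participant: str
    group: str
    shift_results: list[TrialShiftResult]
    saccades: pd.DataFrame           # up-sampled peak velocities, or empty
    arousal_skipped: bool


def process_session(session: Session, config: RunConfig) -> SessionResult:
    """Detect events per trial epoch and extract shift + arousal measures.

    Events are detected within each trial's 2.5 s epoch (gaze re-centres
    between trials, so epochs are independent).  Peak velocities are
    re-estimated on the spline up-sampled stream; for 60 Hz recordings the
    arousal stage is skipped with a logged reason, as peak velocity cannot
    be recovered at that rate.
    """
    rec = session.recording
    shift_results: list[TrialShiftResult] = []
    sacc_frames: list[pd.DataFrame] = []
    arousal_skipped = rec.rate == 60
    if arousal_skipped:
        log.info("%s: 60 Hz recording; arousal stage skipped "
                 "(peak velocity unrecoverable at 60 Hz)",
                 session.participant)
    for row in session.trials.itertuples():
        t0 = row.stim_onset - 1.0    # trial start (1 s pre-stimulus epoch)
        epoch = rec.slice_time(t0, t0 + TRIAL_S)
        aois = aoi_layout(row.condition)
        events = classify_ivt(epoch, config.ivt)
        valid = trial_validity(epoch, row.stim_onset, row.condition, aois,
                               min_valid_frac=config.min_valid_frac)
        if valid:
            res = first_gaze_shift(events, row.stim_onset, row.condition,
                                   aois, trial=row.trial)
        else:
            res = TrialShiftResult(trial=row.trial, condition=row.condition,
                                   valid=False, shift_made=False,
                                   target="none", latency_ms=float("nan"))
        shift_results.append(res)
        if not arousal_skipped:
            try:
                refined = refine_peak_velocities(epoch, events)
            except SamplingRateError:
                arousal_skipped = True
                continue
            sacc_frames.append(saccade_table(
                refined, participant=session.participant,
                condition=row.condition, trial=row.trial))
    sacc_frames = [f for f in sacc_frames if not f.empty]
    saccades = (pd.concat(sacc_frames, ignore_index=True)
                if sacc_frames else saccade_table([]))
    return SessionResult(session.participant, session.group,
                         shift_results, saccades, arousal_skipped)


def build_summaries(session_results: list[SessionResult],
                    config: RunConfig) -> pd.DataFrame:
    """Participant x condition summary table for the mixed models.

    Columns: participant, group, condition, n_valid, prop_shift,
    mean_latency_ms, mean_ratio, included.  Participants with fewer than
    ``min_valid_trials`` valid trials in a condition are dropped from that
    condition.
    """
    rows = []
    for sr in session_results:
        summaries = summarize_participant(
            sr.shift_results, participant=sr.participant, group=sr.group,
            min_valid_trials=config.min_valid_trials)
        ratios = {r.condition: r.mean_ratio
                  for r in peak_velocity_ratio(sr.saccades,
                                               config.amplitude_min)
                  if r.defined}
        for s in summaries:
            s.mean_ratio = ratios.get(s.condition, float("nan"))
            rows.append(vars(s))
    df = pd.DataFrame(rows)
    return df[df["included"]].reset_index(drop=True) if not df.empty else df


#: The planned contrasts for a two-group cohort, mirroring an
#: omnibus-then-follow-up workflow: each entry is
#: (name, outcome, full formula, null formula, subset query or None).
def default_contrasts(groups: tuple[str, str] = ("WS", "TD")):
    g1, g2 = groups
    plan = [
        ("interaction_group_x_region", "prop_shift",
         "prop_shift ~ C(group) * C(condition)",
         "prop_shift ~ C(group) + C(condition)", None),
        ("group_shift_to_eyes", "prop_shift",
         "prop_shift ~ C(group)", "prop_shift ~ 1",
         "condition == 'mouth_cued'"),
        ("group_shift_from_eyes", "prop_shift",
         "prop_shift ~ C(group)", "prop_shift ~ 1",
         "condition == 'eyes_cued'"),
        ("group_latency_to_eyes", "mean_latency_ms",
         "mean_latency_ms ~ C(group)", "mean_latency_ms ~ 1",
         "condition == 'mouth_cued'"),
        ("group_ratio", "mean_ratio",
         "mean_ratio ~ C(group) + C(condition)",
         "mean_ratio ~ C(condition)", None),
    ]
    for g in groups:
        plan.append((f"bias_within_{g}", "prop_shift",
                     "prop_shift ~ C(condition)", "prop_shift ~ 1",
                     f"group == '{g}'"))
    return plan


def analyze_summaries(summaries: pd.DataFrame, contrasts,
                      fdr_q: float = 0.05) -> list[ComparisonResult]:
    """Fit each planned full/null pair and compare; BH flags across the set."""
    results: list[ComparisonResult] = []
    for name, outcome, full_f, null_f, query in contrasts:
        df = summaries.query(query) if query else summaries
        df = df.dropna(subset=[outcome])
        if df.empty or df["participant"].nunique() < 2:
            log.warning("contrast %s: no usable data, skipped", name)
            continue
        full = fit_random_intercept(df, full_f)
        null = fit_random_intercept(df, null_f)
        results.append(compare_models(full, null, name=name))
    return attach_bh(results, q=fdr_q)


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    return df.rename(columns={"name": "contrast", "passes_bh": "bh_pass"})


@dataclass
class RunBundle:
    summaries: pd.DataFrame
    results: pd.DataFrame
    session_results: list[SessionResult]
    qc_latency_r: float


def run_pipeline(config: RunConfig) -> RunBundle:
    """Simulate a cohort (or use provided sessions) and run every stage.

    Deterministic given the config seed.  When ``out_dir`` is set, writes
    summaries.csv, results.csv, saccades.csv and manifest.json.
    """
    if config.cohort is None:
        raise ValueError("run_pipeline requires a cohort config")
    from dataclasses import replace
    sessions = simulate_cohort(replace(config.cohort, seed=config.seed))
    session_results = [process_session(s, config) for s in sessions]
    summaries = build_summaries(session_results, config)
    group_names = tuple(dict.fromkeys(summaries["group"]))
    contrasts = default_contrasts(group_names[:2]) if len(group_names) >= 2 \
        else []
    results = results_frame(analyze_summaries(summaries, contrasts,
                                              fdr_q=config.fdr_q))
    all_shifts = [r for sr in session_results for r in sr.shift_results]
    qc_r = latency_agreement(all_shifts)
    bundle = RunBundle(summaries, results, session_results, qc_r)
    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: RunBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summaries.to_csv(out / "summaries.csv", index=False)
    bundle.results.to_csv(out / "results.csv", index=False)
    sacc = pd.concat([sr.saccades for sr in bundle.session_results],
                     ignore_index=True)
    sacc.to_csv(out / "saccades.csv", index=False)
    manifest = {
        "package": "gazeorient",
        "version": __version__,
        "seed": config.seed,
        "qc_latency_agreement_r": bundle.qc_latency_r,
        "config": _jsonable(asdict(config)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
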