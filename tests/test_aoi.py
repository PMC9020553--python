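"""AOI assignment, trial validity, first gaze shifts, and summaries."""
import numpy as np
import pytest

import gazeorient as go
from gazeorient.aoi import TrialShiftResult
from gazeorient.ivt import IVTConfig, OculomotorEvent
from gazeorient.pipeline import RunConfig, process_session


AOIS = go.aoi_layout("mouth_cued")   # mouth at origin, eyes at (0, -5)


def shift_result(**kw):
    base = dict(trial=0, condition="mouth_cued", valid=True, shift_made=True,
                target="eyes", latency_ms=400.0, latency_any_ms=400.0)
    base.update(kw)
    return TrialShiftResult(**base)


class TestAssignAOI:
    def test_aoi_centres(self):
        assert go.assign_aoi(*AOIS.eyes.center, AOIS) == "eyes"
        assert go.assign_aoi(*AOIS.mouth.center, AOIS) == "mouth"

    def test_edge_is_inclusive(self):
        assert go.assign_aoi(AOIS.mouth.x_max, AOIS.mouth.y_max,
                             AOIS) == "mouth"

    def test_point_outside_both(self):
        assert go.assign_aoi(20.0, 20.0, AOIS) == "outside"


def epoch_recording(x0=0.0, y0=0.0, rate=120.0, valid_frac=1.0, seed=0):
    """2.5 s trial epoch resting at (x0, y0), optional invalid samples."""
    n = int(2.5 * rate)
    t = np.arange(n) / rate
    valid = np.ones(n, dtype=bool)
    if valid_frac < 1.0:
        r = np.random.default_rng(seed)
        valid[t >= 1.0] = r.random((t >= 1.0).sum()) < valid_frac
    x = np.where(valid, x0, np.nan)
    y = np.where(valid, y0, np.nan)
    return go.GazeRecording(t, x, y, valid, rate)


class TestTrialValidity:
    def test_cued_gaze_full_validity_is_valid(self):
        rec = epoch_recording()       # at mouth centre
        assert go.trial_validity(rec, 1.0, "mouth_cued", AOIS)

    def test_gaze_on_wrong_aoi_at_onset_is_invalid(self):
        rec = epoch_recording(0.0, -5.0)    # on the eyes in a mouth-cued trial
        assert not go.trial_validity(rec, 1.0, "mouth_cued", AOIS)

    def test_too_few_valid_samples_is_invalid(self):
        rec = epoch_recording(valid_frac=0.3)
        assert not go.trial_validity(rec, 1.0, "mouth_cued", AOIS)


def make_saccade_event(onset, start, end):
    return OculomotorEvent("saccade", onset, onset + 0.04,
                           float(np.hypot(end[0] - start[0],
                                          end[1] - start[1])), 300.0,
                           start_x=start[0], start_y=start[1],
                           end_x=end[0], end_y=end[1])


class TestFirstGazeShift:
    def test_no_leaving_saccade_means_no_shift(self):
        events = [OculomotorEvent("fixation", 1.0, 2.5, 0.1, 5.0,
                                  centroid_x=0.0, centroid_y=0.0)]
        res = go.first_gaze_shift(events, 1.0, "mouth_cued", AOIS)
        assert not res.shift_made
        assert res.target == "none"
        assert np.isnan(res.latency_ms)

    def test_shift_to_eyes_latency_anchored_to_onset(self):
        events = [make_saccade_event(1.4, (0.0, 0.0), (0.0, -5.0))]
        res = go.first_gaze_shift(events, 1.0, "mouth_cued", AOIS)
        assert res.shift_made and res.target == "eyes"
        assert res.latency_ms == pytest.approx(400.0)

    def test_landing_outside_both_is_excluded_target(self):
        events = [make_saccade_event(1.3, (0.0, 0.0), (15.0, 15.0))]
        res = go.first_gaze_shift(events, 1.0, "mouth_cued", AOIS)
        assert res.target == "outside"
        assert not res.shift_made
        assert res.latency_any_ms == pytest.approx(300.0)

    def test_later_aoi_entry_defines_qc_latency(self):
        events = [make_saccade_event(1.3, (0.0, 0.0), (15.0, 15.0)),
                  make_saccade_event(1.6, (15.0, 15.0), (0.0, -5.0))]
        res = go.first_gaze_shift(events, 1.0, "mouth_cued", AOIS)
        assert res.target == "outside"
        assert res.latency_ms == pytest.approx(600.0)
        assert res.latency_any_ms == pytest.approx(300.0)

    def test_anticipatory_shift_flagged_but_retained(self):
        events = [make_saccade_event(1.05, (0.0, 0.0), (0.0, -5.0))]
        res = go.first_gaze_shift(events, 1.0, "mouth_cued", AOIS)
        assert res.shift_made and res.anticipatory

    def test_simulated_trial_latency_recovered(self, noiseless_params, rng):
        config = RunConfig(ivt=IVTConfig())
        session = go.simulate_session(noiseless_params, rng)
        sr = process_session(session, config)
        truth = session.truth.set_index("trial")
        errors = []
        for res in sr.shift_results:
            true_row = truth.loc[res.trial]
            assert res.shift_made == bool(true_row["shift_made"])
            if res.shift_made:
                errors.append(abs(res.latency_ms / 1000.0
                                  - true_row["latency"]))
        # latency recovery bias at most one sample period on noiseless data
        assert np.mean(errors) <= 1.0 / 120


class TestSummaries:
    def test_proportion_arithmetic(self):
        results = [shift_result(trial=i, shift_made=i < 6,
                                target="eyes" if i < 6 else "none",
                                latency_ms=400.0 if i < 6 else np.nan)
                   for i in range(10)]
        (s,) = go.summarize_participant(results)
        assert s.n_valid == 10
        assert s.prop_shift == pytest.approx(0.6)
        assert s.mean_latency_ms == pytest.approx(400.0)

    def test_fewer_than_five_valid_trials_excluded(self):
        results = [shift_result(trial=i, condition="eyes_cued",
                                target="mouth") for i in range(4)]
        (s,) = go.summarize_participant(results)
        assert not s.included
        assert go.summaries_frame([s]).empty

    def test_outside_landings_removed_from_both_sides(self):
        results = ([shift_result(trial=i) for i in range(4)]
                   + [shift_result(trial=4, shift_made=False,
                                   target="outside", latency_ms=np.nan)]
                   + [shift_result(trial=5, shift_made=False, target="none",
                                   latency_ms=np.nan)])
        (s,) = go.summarize_participant(results)
        assert s.n_valid == 6
        assert s.prop_shift == pytest.approx(4 / 5)   # outside trial dropped

    def test_zero_shifts_latency_undefined(self):
        results = [shift_result(trial=i, shift_made=False, target="none",
                                latency_ms=np.nan) for i in range(6)]
        (s,) = go.summarize_participant(results)
        assert s.prop_shift == 0.0
        assert np.isnan(s.mean_latency_ms)

    def test_prop_shift_consistent_with_generating_probability(self):
        # 300 trials/participant: recovered proportion approaches p_shift
        params = go.ParticipantParams(p_shift_to_eyes=0.7,
                                      p_shift_from_eyes=0.7,
                                      noise_sd=0.0, dropout=0.0)
        session = go.simulate_session(params, np.random.default_rng(3),
                                      n_trials=300)
        sr = process_session(session, RunConfig(ivt=IVTConfig()))
        for s in go.summarize_participant(sr.shift_results):
            assert s.prop_shift == pytest.approx(0.7, abs=0.09)


class TestLatencyAgreement:
    def test_identical_latency_vectors_r_one(self):
        results = [shift_result(trial=i, latency_ms=300.0 + 50 * i,
                                latency_any_ms=300.0 + 50 * i)
                   for i in range(5)]
        assert go.latency_agreement(results) == pytest.approx(1.0)

    def test_orthogonal_toy_vectors_r_zero(self):
        lat_aoi = [300.0, 400.0, 300.0, 400.0]
        lat_any = [100.0, 100.0, 200.0, 200.0]
        results = [shift_result(trial=i, latency_ms=a, latency_any_ms=b)
                   for i, (a, b) in enumerate(zip(lat_aoi, lat_any))]
        assert go.latency_agreement(results) == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_pairs_undefined(self):
        results = [shift_result(trial=0), shift_result(trial=1)]
        assert np.isnan(go.latency_agreement(results))

    def test_simulated_cohort_r_near_one(self, default_params, rng):
        # nearly all first shifts land in the other AOI by construction
        session = go.simulate_session(default_params, rng)
        sr = process_session(session, RunConfig())
        r = go.latency_agreement(sr.shift_results)
        assert r > 0.95
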