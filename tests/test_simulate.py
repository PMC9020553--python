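"""Synthetic gaze generator: kinematic oracles and paradigm structure."""
import numpy as np
import pytest

import gazeorient as go
from gazeorient.simulate import (EMOTIONS, N_TRIALS, PRE_STIMULUS_S,
                                 STIMULUS_S, TRIAL_S, _session_plan)


class TestSaccadeKinematics:
    def test_zero_amplitude_is_stationary(self):
        t, dx, dy = go.simulate_saccade(0.0, 0.05, 1200)
        assert np.all(dx == 0.0)
        assert np.all(dy == 0.0)

    def test_peak_velocity_closed_form(self):
        # A = 8 deg, D = 50 ms -> V_p = 2A/D = 320 deg/s, V_p/A = 40 /s
        prof = go.SaccadeProfile(onset=0.0, amplitude=8.0, duration=0.05,
                                 direction=(1.0, 0.0))
        assert prof.peak_velocity == pytest.approx(320.0)
        assert prof.peak_velocity / prof.amplitude == pytest.approx(40.0)

    def test_total_displacement_equals_amplitude(self):
        t, dx, dy = go.simulate_saccade(8.0, 0.05, 1200)
        assert np.hypot(dx[-1], dy[-1]) == pytest.approx(8.0, abs=1e-6)

    def test_velocity_quadrature_recovers_amplitude(self):
        # integral of the sampled 1200 Hz velocity profile ~ A within 0.5%
        A, D = 8.0, 0.05
        t, dx, dy = go.simulate_saccade(A, D, 1200)
        v = (A / D) * (1 - np.cos(2 * np.pi * np.clip(t / D, 0, 1)))
        assert np.trapezoid(v, t) == pytest.approx(A, rel=5e-3)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            go.simulate_saccade(5.0, 0.0, 120)

    def test_main_sequence_ratio_decreases_with_amplitude(self):
        # D = D0 + k A implies V_p / A = 2 / D decreasing in A
        amplitudes = np.linspace(1, 15, 20)
        ratios = [2.0 / go.main_sequence_duration(a) for a in amplitudes]
        assert np.all(np.diff(ratios) < 0)

    def test_velocity_scale_inflates_duration(self):
        d_full = go.main_sequence_duration(5.0)
        d_slow = go.main_sequence_duration(5.0, velocity_scale=0.75)
        assert d_slow == pytest.approx(d_full / 0.75)
        # scaled peak velocity at fixed amplitude
        assert 2 * 5.0 / d_slow == pytest.approx(0.75 * 2 * 5.0 / d_full)


class TestTrialStructure:
    def test_epoch_durations(self, noiseless_params, rng):
        assert PRE_STIMULUS_S == 1.0
        assert STIMULUS_S == 1.5
        t, x, y, valid, truth = go.simulate_trial(
            "eyes_cued", "neutral", 0, noiseless_params, rng)
        assert len(t) == int(TRIAL_S * noiseless_params.rate)
        assert truth["stim_onset"] == pytest.approx(1.0)

    def test_shift_probability_zero_stays_in_cued_aoi(self, rng):
        params = go.ParticipantParams(p_shift_to_eyes=0.0,
                                      p_shift_from_eyes=0.0,
                                      noise_sd=0.0, dropout=0.0)
        for cond in ("eyes_cued", "mouth_cued"):
            t, x, y, valid, truth = go.simulate_trial(
                cond, "happy", 1, params, rng)
            assert not truth["shift_made"]
            aois = go.aoi_layout(cond)
            cued = aois.eyes if cond == "eyes_cued" else aois.mouth
            assert np.all(cued.contains(x, y))

    def test_certain_shift_records_ground_truth(self, noiseless_params, rng):
        t, x, y, valid, truth = go.simulate_trial(
            "mouth_cued", "angry", 2, noiseless_params, rng)
        assert truth["shift_made"]
        assert truth["target"] == "eyes"
        assert 0.1 <= truth["latency"] <= 1.3
        assert truth["amplitude"] == pytest.approx(5.0)
        assert truth["peak_velocity"] == pytest.approx(
            2 * truth["amplitude"] / truth["duration"])

    def test_ground_truth_consistent_with_samples(self, noiseless_params,
                                                  rng):
        # noiseless: final displacement equals the true amplitude
        t, x, y, valid, truth = go.simulate_trial(
            "eyes_cued", "neutral", 3, noiseless_params, rng)
        disp = np.hypot(x[-1] - x[0], y[-1] - y[0])
        assert disp == pytest.approx(truth["amplitude"], abs=1e-9)


class TestSessionStructure:
    def test_sixty_trials_balanced(self, default_params, rng):
        s = go.simulate_session(default_params, rng)
        assert len(s.trials) == N_TRIALS == 60
        counts = s.trials["condition"].value_counts()
        assert counts["eyes_cued"] == counts["mouth_cued"] == 30
        emo = s.trials["emotion"].value_counts()
        assert all(emo[e] == 20 for e in EMOTIONS)
        actors = s.trials["actor"].value_counts()
        assert len(actors) == 10 and all(actors == 6)

    def test_actor_emotion_fully_crossed(self):
        plan = _session_plan(60)
        cells = {(a, e) for _, a, e in plan}
        assert len(cells) == 30  # 10 actors x 3 emotions

    def test_same_seed_reproduces_byte_identical_output(self, default_params):
        s1 = go.simulate_session(default_params,
                                 np.random.default_rng(99))
        s2 = go.simulate_session(default_params,
                                 np.random.default_rng(99))
        assert np.array_equal(s1.recording.x, s2.recording.x,
                              equal_nan=True)
        assert s1.truth.equals(s2.truth)

    def test_distinct_seeds_differ(self, default_params):
        s1 = go.simulate_session(default_params, np.random.default_rng(1))
        s2 = go.simulate_session(default_params, np.random.default_rng(2))
        assert not np.array_equal(s1.recording.x, s2.recording.x,
                                  equal_nan=True)


class TestCohort:
    def test_group_sizes_honoured(self):
        cfg = go.CohortConfig(groups=(go.GroupConfig(name="A", n=3),
                                      go.GroupConfig(name="B", n=4)),
                              seed=0)
        sessions = go.simulate_cohort(cfg)
        assert len(sessions) == 7
        assert sum(s.group == "A" for s in sessions) == 3

    def test_cohort_reproducible_from_seed(self):
        cfg = go.CohortConfig(groups=(go.GroupConfig(name="A", n=2),), seed=5)
        a = go.simulate_cohort(cfg)
        b = go.simulate_cohort(cfg)
        assert np.array_equal(a[0].recording.x, b[0].recording.x,
                              equal_nan=True)
        assert a[1].truth.equals(b[1].truth)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            go.GroupConfig(name="A", n=2, p_shift_to_eyes=1.5)

    def test_velocity_scaling_recovered_in_ground_truth(self):
        # ratio V_p/A in ground truth scales by the group's velocity factor
        cfg = go.CohortConfig(
            groups=(go.GroupConfig(name="slow", n=8, velocity_scale=0.75,
                                   velocity_scale_sd=0.0),
                    go.GroupConfig(name="full", n=8, velocity_scale=1.0,
                                   velocity_scale_sd=0.0)),
            seed=11)
        ratios = {"slow": [], "full": []}
        for s in go.simulate_cohort(cfg):
            shifted = s.truth[s.truth["shift_made"]]
            ratios[s.group].extend(
                (shifted["peak_velocity"] / shifted["amplitude"]).tolist())
        observed = np.mean(ratios["slow"]) / np.mean(ratios["full"])
        assert observed == pytest.approx(0.75, abs=0.02)

    def test_null_cohort_groups_indistinguishable(self):
        # no injected effect: per-seed two-sample t-tests on the ground-truth
        # shift proportion should not reject at much above the nominal rate
        from scipy import stats
        pvals = []
        for seed in range(20):
            cfg = go.CohortConfig(
                groups=(go.GroupConfig(name="A", n=6),
                        go.GroupConfig(name="B", n=6)), seed=seed)
            props = {"A": [], "B": []}
            for s in go.simulate_cohort(cfg):
                props[s.group].append(s.truth["shift_made"].mean())
            pvals.append(stats.ttest_ind(props["A"], props["B"]).pvalue)
        assert np.mean(np.array(pvals) < 0.05) <= 0.25
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
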