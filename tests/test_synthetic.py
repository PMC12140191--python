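"""Tests of the synthetic cohort generator: stroke schedules, trial
dynamics, cohort writing, and reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats as sps

import pawshift as ps
from pawshift import CohortModel, TrialTimeline
from pawshift.errors import DesignError, ParameterError
from pawshift.synthetic import mouse_baseline_offset


class TestStrokeSchedule:
    def test_intervals_within_bounds_many_seeds(self):
        """Every generated train respects the interval law and the window."""
        for seed in range(1000):
            sched = ps.sample_stroke_schedule(120.0, 0.6, 2.0, "synchronous", seed=seed)
            sched.validate(120.0, 0.6, 2.0)
            assert sched.synchronous

    def test_asynchronous_trains_differ(self):
        sched = ps.sample_stroke_schedule(120.0, 0.6, 2.0, "asynchronous", seed=7)
        sched.validate(120.0, 0.6, 2.0)
        assert not sched.synchronous

    def test_degenerate_interval_law_gives_1hz_train(self):
        """min = max = 1 s produces the deterministic 1 Hz train: 119 strokes
        fit in the 120 s window (the 120th would end past it)."""
        sched = ps.sample_stroke_schedule(120.0, 1.0, 1.0, "synchronous", seed=0)
        assert len(sched.visual_onsets) == 119
        np.testing.assert_allclose(sched.visual_onsets, np.arange(1, 120, dtype=float))
        np.testing.assert_array_equal(sched.visual_onsets, sched.tactile_onsets)

    def test_onset_count_matches_renewal_rate(self):
        """Mean onset count ~ duration / E[interval], E[interval] computed by
        numerically integrating the truncated-exponential density, and
        cross-checked against 10^6 direct draws."""
        lo, hi, rate = 0.6, 2.0, 1.0
        norm = np.exp(-rate * lo) - np.exp(-rate * hi)
        density = lambda x: rate * np.exp(-rate * x) / norm
        e_iv, _ = integrate.quad(lambda x: x * density(x), lo, hi)
        v_iv, _ = integrate.quad(lambda x: (x - e_iv) ** 2 * density(x), lo, hi)
        # oracle: direct draws from the same law via scipy
        draws = sps.truncexpon(b=(hi - lo) * rate, loc=lo, scale=1.0 / rate).rvs(
            10**6, random_state=123
        )
        assert abs(draws.mean() - e_iv) < 4 * np.sqrt(v_iv / 10**6)

        counts = []
        for seed in range(300):
            sched = ps.sample_stroke_schedule(120.0, lo, hi, "asynchronous", seed=seed)
            counts.extend([len(sched.visual_onsets), len(sched.tactile_onsets)])
        counts = np.asarray(counts, float)
        # renewal theory: count of onsets ending by T lies within one renewal
        # of (T - stroke)/E[interval]
        target = (120.0 - 0.3) / e_iv
        sem = counts.std(ddof=1) / np.sqrt(counts.size)
        assert target - 1 - 4 * sem <= counts.mean() <= target + 4 * sem

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(min_interval=0.0, max_interval=2.0),
            dict(min_interval=2.0, max_interval=0.6),
            dict(min_interval=-1.0, max_interval=2.0),
        ],
    )
    def test_invalid_interval_bounds_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ps.sample_stroke_schedule(120.0, mode="synchronous", **kwargs)

    def test_pairing_window_must_exceed_max_interval(self):
        with pytest.raises(ParameterError):
            ps.sample_stroke_schedule(1.0, 0.6, 2.0, "synchronous", seed=0)


def _zero_model(**overrides):
    base = dict(
        n_mice=1,
        n_sessions=1,
        baseline_offset_sd=0.0,
        baseline_noise_sd=0.0,
        measurement_noise_sd=0.0,
        fast_amplitude=0.0,
        sustained_amplitudes={},
        dilation_amplitude=0.0,
        ear_burst_sd=0.0,
        whisker_burst_sd=0.0,
        check_amplitude_ordering=False,
        seed=3,
    )
    base.update(overrides)
    return CohortModel(**base)


class TestSimulateTrial:
    def test_zero_noise_zero_effect_is_constant(self, fast_timeline):
        rec = ps.simulate_trial(
            _zero_model(), "m01", 1, "artificial_limb", "synchronous", timeline=fast_timeline
        )
        for name, track in rec.tracks.items():
            assert np.ptp(track.x) == 0.0, name
            assert np.ptp(track.y) == 0.0, name
            assert (track.confidence == 1.0).all()

    def test_sustained_component_recovers_mean(self):
        """Monte-Carlo oracle: over many trials, the mean of the horizontal
        pupil signal on the sustained plateau equals offset + amplitude."""
        amp, sigma = 2.0, 0.5
        timeline = TrialTimeline(
            pairing_start=5.0, threat_onset=10.0, threat_hold=8.0, frame_rate=100.0
        )
        model = _zero_model(
            baseline_noise_sd=sigma,
            sustained_amplitudes={("artificial_limb", "synchronous"): amp},
        )
        i0 = timeline.frame_of(timeline.threat_onset + model.sustained_onset)
        i1 = timeline.frame_of(
            timeline.threat_onset + model.sustained_onset + model.sustained_duration
        )
        n_trials = 1000
        means = np.empty(n_trials)
        for r in range(n_trials):
            rec = ps.simulate_trial(
                model, "m01", 1, "artificial_limb", "synchronous",
                seed=r, timeline=timeline, parts=["right_pupil_center"],
            )
            means[r] = rec.tracks["right_pupil_center"].x[i0:i1].mean()
        base_x = ps.simulate_trial(
            _zero_model(), "m01", 1, "artificial_limb", "synchronous",
            timeline=timeline, parts=["right_pupil_center"],
        ).tracks["right_pupil_center"].x[0]
        assert abs(means.mean() - base_x - amp) < 4 * sigma / np.sqrt(n_trials)

    def test_threat_only_trial_has_no_schedule_and_small_reflex(self, fast_timeline):
        model = _zero_model(
            fast_amplitude=8.0,
            none_fast_scale=0.15,
            sustained_amplitudes={("none", "none"): 0.1},
        )
        rec = ps.simulate_trial(model, "m01", 1, "none", "none", timeline=fast_timeline)
        assert rec.schedule is None
        x = rec.tracks["right_pupil_center"].x
        dev = np.abs(x - x[0]).max()
        assert 0.0 < dev <= 0.15 * 8.0 + 0.1 + 1e-9

    def test_paired_trial_carries_schedule(self, fast_timeline, small_model):
        rec = ps.simulate_trial(
            small_model, "m01", 1, "artificial_limb", "asynchronous", timeline=fast_timeline
        )
        assert rec.schedule is not None
        rec.schedule.validate(
            fast_timeline.pairing_duration, small_model.min_interval, small_model.max_interval
        )

    def test_unknown_condition_rejected(self, fast_timeline, small_model):
        with pytest.raises(ParameterError):
            ps.simulate_trial(small_model, "m01", 1, "banana", "synchronous",
                              timeline=fast_timeline)
        with pytest.raises(ParameterError):
            ps.simulate_trial(small_model, "m01", 1, "none", "synchronous",
                              timeline=fast_timeline)

    def test_bit_reproducible(self, fast_timeline, small_model):
        a = ps.simulate_trial(small_model, "m02", 2, "block", "synchronous",
                              timeline=fast_timeline)
        b = ps.simulate_trial(small_model, "m02", 2, "block", "synchronous",
                              timeline=fast_timeline)
        for name in a.tracks:
            np.testing.assert_array_equal(a.tracks[name].x, b.tracks[name].x)
            np.testing.assert_array_equal(a.tracks[name].y, b.tracks[name].y)

    def test_parts_subset_is_bit_identical_to_full(self, fast_timeline, small_model):
        full = ps.simulate_trial(small_model, "m01", 1, "artificial_limb", "synchronous",
                                 timeline=fast_timeline)
        sub = ps.simulate_trial(small_model, "m01", 1, "artificial_limb", "synchronous",
                                timeline=fast_timeline, parts=["left_ear", "right_pupil_center"])
        assert set(sub.tracks) == {"left_ear", "right_pupil_center"}
        for name in sub.tracks:
            np.testing.assert_array_equal(full.tracks[name].x, sub.tracks[name].x)

    def test_baseline_is_stationary(self):
        """First- and second-half baseline means agree within 5 sd of the
        mean-difference estimator (OU: var(mean over T) ~ sd^2 * 2 tau / T)."""
        model = CohortModel(seed=21)
        rec = ps.simulate_trial(model, "m01", 1, "artificial_limb", "synchronous",
                                parts=["right_pupil_center"])
        timeline = rec.timeline
        n_base = timeline.frame_of(timeline.pairing_start)
        x = rec.tracks["right_pupil_center"].x[:n_base]
        half = n_base // 2
        t_half = half / timeline.frame_rate
        sd_mean = model.baseline_noise_sd * np.sqrt(
            2 * model.baseline_noise_corr_time / t_half
        )
        sd_diff = np.sqrt(2) * sd_mean
        assert abs(x[:half].mean() - x[half:].mean()) < 5 * sd_diff

    def test_sign_config_flips_response_exactly(self, fast_timeline):
        model = _zero_model(
            fast_amplitude=4.0,
            sustained_amplitudes={("artificial_limb", "synchronous"): 2.0},
        )
        flipped = dataclasses.replace(
            model, toward_threat_sign={"right": -1.0, "left": 1.0}
        )
        a = ps.simulate_trial(model, "m01", 1, "artificial_limb", "synchronous",
                              timeline=fast_timeline, parts=["right_pupil_center"])
        b = ps.simulate_trial(flipped, "m01", 1, "artificial_limb", "synchronous",
                              timeline=fast_timeline, parts=["right_pupil_center"])
        xa = a.tracks["right_pupil_center"].x
        xb = b.tracks["right_pupil_center"].x
        np.testing.assert_allclose(xa - xa[0], -(xb - xb[0]))

    def test_offset_shared_across_sessions(self, small_model, fast_timeline):
        off = mouse_baseline_offset(small_model, "m01")
        for session in (1, 2):
            rec = ps.simulate_trial(
                _zero_model(seed=small_model.seed, baseline_offset_sd=5.0),
                "m01", session, "artificial_limb", "synchronous",
                timeline=fast_timeline, parts=["right_pupil_center"],
            )
            assert rec.tracks["right_pupil_center"].x[0] == pytest.approx(760.0 + off)

    def test_amplitude_ordering_enforced(self):
        with pytest.raises(ParameterError):
            CohortModel(
                sustained_amplitudes={
                    ("artificial_limb", "synchronous"): 1.0,
                    ("artificial_limb", "asynchronous"): 2.0,
                    ("block", "synchronous"): 0.5,
                    ("block", "asynchronous"): 0.4,
                    ("none", "none"): 0.1,
                }
            )


class TestSimulateCohort:
    def test_full_design_writes_100_trials_200_files(self, tmp_path):
        """Ten mice x five sessions x two trials -> 100 trials, 200 files."""
        timeline = TrialTimeline(pairing_start=12.0, threat_onset=24.0,
                                 threat_hold=4.0, frame_rate=5.0)
        model = CohortModel(n_mice=10, n_sessions=5, seed=1)
        manifest = ps.simulate_cohort(model, output_dir=tmp_path, timeline=timeline)
        assert len(manifest.trials) == 100
        csvs = [p for p in tmp_path.iterdir() if p.suffix == ".csv"]
        assert len(csvs) == 200
        assert manifest.n_mice == 10

    def test_empty_design(self, tmp_path):
        model = CohortModel(n_mice=0, n_sessions=5, seed=1)
        manifest = ps.simulate_cohort(model, output_dir=tmp_path)
        assert manifest.trials == []
        assert not [p for p in tmp_path.iterdir() if p.suffix == ".csv"]

    def test_excluded_mouse_leaves_nine(self, tmp_path, fast_timeline):
        timeline = dataclasses.replace(fast_timeline, frame_rate=5.0)
        design = ps.default_design(10, 1, exclude_mice=["m10"])
        model = CohortModel(n_mice=10, n_sessions=1, seed=1)
        manifest = ps.simulate_cohort(model, design, tmp_path, timeline=timeline)
        assert manifest.n_mice == 9
        assert "m10" not in manifest.mouse_ids

    def test_excluded_trial_flagged_without_files(self, tmp_path, fast_timeline):
        timeline = dataclasses.replace(fast_timeline, frame_rate=5.0)
        design = ps.default_design(2, 2, exclude_trials=[("m02", 2)])
        model = CohortModel(n_mice=2, n_sessions=2, seed=1)
        manifest = ps.simulate_cohort(model, design, tmp_path, timeline=timeline)
        flagged = [t for t in manifest.trials if t.excluded]
        assert {(t.mouse_id, t.session_index) for t in flagged} == {("m02", 2)}
        assert all(v is None for t in flagged for v in t.files.values())

    def test_duplicate_design_rows_rejected(self, tmp_path, small_model):
        import pandas as pd

        design = ps.default_design(1, 1)
        design = pd.concat([design, design.iloc[[0]]], ignore_index=True)
        with pytest.raises(DesignError):
            ps.simulate_cohort(small_model, design, tmp_path)

    def test_cohort_bit_reproducible(self, tmp_path, fast_timeline):
        timeline = dataclasses.replace(fast_timeline, frame_rate=5.0)
        model = CohortModel(n_mice=1, n_sessions=1, seed=9)
        m1 = ps.simulate_cohort(model, output_dir=tmp_path / "a", timeline=timeline)
        ps.simulate_cohort(model, output_dir=tmp_path / "b", timeline=timeline)
        name = m1.trials[0].files["right"]
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert (tmp_path / "a" / "manifest.yaml").read_bytes() == (
            tmp_path / "b" / "manifest.yaml"
        ).read_bytes()
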