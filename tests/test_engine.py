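import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from labclock import (
    TrialSpec,
    VirtualClock,
    angle_to_time,
    run_experiment,
    run_trial,
    sample_initial_delay,
    scramble_trials,
    time_to_angle,
    wrapped_diff,
    write_results,
    results_to_resultset,
    build_experiment1_config,
    ParticipantModel,
)


def brute_force_wrapped(judged, actual, cycle):
    """Independent oracle: minimize |judged + k*cycle - actual| over k."""
    k0 = round((actual - judged) / cycle)
    candidates = [judged - actual + k * cycle for k in range(k0 - 2, k0 + 3)]
    best = min(candidates, key=lambda d: (abs(d), -d))  # tie -> positive
    return best


class TestGeometry:
    @pytest.mark.parametrize("angle, cycle, expected", [
        (0, 2560, 0),
        (180, 2560, 1280),
        (45, 2560, 320),  # proportional: 45/360 * 2560
        (360 + 45, 2560, 320),  # normalization modulo 360
        (-90, 2560, 1920),
    ])
    def test_angle_to_time_linear_sweep(self, angle, cycle, expected):
        assert angle_to_time(angle, cycle) == pytest.approx(expected)

    def test_angle_time_round_trip(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 2560, 100)
        assert np.allclose(angle_to_time(time_to_angle(times, 2560), 2560), times)

    def test_nonpositive_cycle_rejected(self):
        with pytest.raises(ValueError):
            angle_to_time(10, 0)

    @pytest.mark.parametrize("judged, actual, cycle, expected", [
        (137.5, 137.5, 2560, 0.0),
        (10, 2550, 2560, 20.0),     # wrap across 12 o'clock
        (1290, 10, 2560, 1280.0),   # exact half-cycle tie -> +cycle/2
        (10, 1290, 2560, 1280.0),   # tie from the other side also -> +
    ])
    def test_wrapped_diff_examples(self, judged, actual, cycle, expected):
        assert wrapped_diff(judged, actual, cycle) == pytest.approx(expected)

    @given(st.floats(0, 10_000), st.floats(0, 10_000),
           st.floats(1.0, 5000.0))
    @settings(max_examples=300, deadline=None)
    def test_wrapped_diff_matches_brute_force(self, judged, actual, cycle):
        got = wrapped_diff(judged, actual, cycle)
        want = brute_force_wrapped(judged, actual, cycle)
        tol = 1e-6 * max(1.0, cycle)
        # near an exact half-cycle tie, rounding may flip the sign between the
        # two computations; magnitude and congruence must always agree
        assert abs(abs(got) - abs(want)) < tol
        resid = (got - (judged - actual)) % cycle
        assert min(resid, cycle - resid) < tol
        assert -cycle / 2 - tol < got <= cycle / 2 + tol


class TestInitialDelay:
    def test_degenerate_interval_is_constant(self):
        assert sample_initial_delay(2000, 2000, seed=99) == 2000

    def test_sample_lies_in_range(self):
        d = sample_initial_delay(1000, 3000, seed=5)
        assert 1000 <= d <= 3000

    def test_min_above_max_raises(self):
        with pytest.raises(ValueError):
            sample_initial_delay(3000, 1000, seed=0)

    def test_mean_matches_uniform_moments(self):
        rng = np.random.default_rng(11)
        draws = np.array([sample_initial_delay(1000, 3000, rng) for _ in range(10_000)])
        se = 2000 / np.sqrt(12) / np.sqrt(10_000)
        assert abs(draws.mean() - 2000) < 3 * se


class TestScramble:
    def test_single_element_unchanged(self):
        trials = [TrialSpec(cycle_ms=2560, tone_delay_ms=1)]
        assert scramble_trials(trials, seed=0) == trials

    def test_preserves_condition_multiset(self):
        cfg = build_experiment1_config(seed=3)
        shuffled = scramble_trials(cfg.phases[0].trials, seed=7)
        delays = [t.tone_delay_ms for t in shuffled]
        assert len(shuffled) == 80
        assert delays.count(1) == 40 and delays.count(500) == 40

    def test_seeded_determinism(self):
        trials = [TrialSpec(tone_delay_ms=d) for d in range(10)]
        assert scramble_trials(trials, seed=4) == scramble_trials(trials, seed=4)
        assert scramble_trials(trials, seed=4) != scramble_trials(trials, seed=5)


class TestRunTrial:
    def setup_method(self):
        self.cfg = build_experiment1_config(seed=1)

    def test_delayed_tone_measured_exactly_under_zero_jitter(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=500)
        out = run_trial(spec, self.cfg, press_script=[3000.0], seed=0)
        assert out.record.tone_time_ms == pytest.approx(500.0)
        assert out.valid_press_ms == 3000.0

    def test_absent_tone_never_yields_tone_time(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=None)
        out = run_trial(spec, self.cfg, press_script=[3000.0], seed=0)
        assert out.record.tone_time_ms is None

    def test_cycle_time_is_two_rotations(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=1)
        out = run_trial(spec, self.cfg, press_script=[3000.0], seed=0)
        assert out.record.cycle_time_ms == pytest.approx(5120.0)

    def test_event_order_invariant(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=500)
        clock = VirtualClock(now_ms=100.0)
        out = run_trial(spec, self.cfg, press_script=[3000.0], clock=clock, seed=0)
        rec = out.record
        rot_start = out.rotation_start_ms
        assert rec.start_trial_time_ms <= rot_start < rot_start + 5120 <= rec.end_trial_time_ms
        assert rec.start_trial_audio_time_s == pytest.approx(rec.start_trial_time_ms / 1000)
        assert rec.initial_random_time_ms == pytest.approx(rot_start - rec.start_trial_time_ms)

    def test_first_rotation_press_logged_but_not_accepted(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=500)
        out = run_trial(spec, self.cfg, press_script=[1000.0], seed=0)
        assert out.valid_press_ms is None
        assert out.press_in_first_rotation
        assert len(out.record.key_press_trial_times_ms) == 1
        assert out.record.tone_time_ms is None  # no accepted press -> no tone

    def test_first_press_in_second_rotation_wins(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=500)
        out = run_trial(spec, self.cfg, press_script=[1000.0, 2800.0, 4000.0], seed=0)
        assert out.valid_press_ms == 2800.0
        assert len(out.record.key_press_trial_times_ms) == 3

    def test_no_press_is_legal_non_response(self):
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=500)
        out = run_trial(spec, self.cfg, press_script=[], seed=0)
        assert out.valid_press_ms is None
        assert out.record.key_press_trial_times_ms == []

    def test_jitter_law_recovered_in_tone_time(self):
        """Measured tone delay minus configured delay follows the injected
        per-event latency law (the in-silico analogue of hardware audio
        latency measurement)."""
        mu, sigma, n = -0.445, 0.542, 500
        rng = np.random.default_rng(21)
        clock = VirtualClock(jitter_mean_ms=mu, jitter_sd_ms=sigma, rng=rng)
        spec = TrialSpec(cycle_ms=2560, tone_delay_ms=500)
        errs = []
        for _ in range(n):
            out = run_trial(spec, self.cfg, press_script=[3000.0], clock=clock, seed=rng)
            errs.append(out.record.tone_time_ms - 500.0)
        errs = np.array(errs)
        assert abs(errs.mean() - mu) < 3 * sigma / np.sqrt(n)
        assert abs(errs.std(ddof=1) - sigma) < 3 * sigma / np.sqrt(2 * n)


class TestRunExperiment:
    def test_full_design_produces_100_outcomes(self):
        cfg = build_experiment1_config(seed=1)
        model = ParticipantModel(bias_ms={}, judgment_sd_ms=0.0)
        results = run_experiment(cfg, model, master_seed=9)
        assert len(results) == 100

    def test_total_miss_model_yields_all_non_responses(self):
        cfg = build_experiment1_config(seed=1)
        model = ParticipantModel(miss_prob=1.0)
        results = run_experiment(cfg, model, master_seed=9)
        assert all(o.valid_press_ms is None for o, _ in results)
        assert all(j.judged_time_ms is None for _, j in results)

    def test_same_seed_gives_byte_identical_results(self):
        cfg = build_experiment1_config(seed=1)
        model = ParticipantModel(bias_ms={1.0: 5, 500.0: 40, "baseline": 0},
                                 judgment_sd_ms=15.0, miss_prob=0.05)
        blobs = []
        for _ in range(2):
            results = run_experiment(cfg, model, master_seed=77)
            rs = results_to_resultset(results, cfg, "A", "P001", 77)
            blobs.append(write_results(rs, "csv"))
        assert blobs[0] == blobs[1]

    def test_scrambled_phase_order_differs_but_multiset_kept(self):
        cfg = build_experiment1_config(seed=1)
        cfg.phases[0].scramble = True
        model = ParticipantModel()
        res_a = run_experiment(cfg, model, master_seed=1)
        res_b = run_experiment(cfg, model, master_seed=2)
        tones_a = [o.record.tone_ms for o, _ in res_a[:80]]
        tones_b = [o.record.tone_ms for o, _ in res_b[:80]]
        assert sorted(tones_a, key=str) == sorted(tones_b, key=str)
        assert tones_a != tones_b
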