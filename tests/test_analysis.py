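import copy
import math

import numpy as np
import pytest
from scipy import stats

from labclock import (
    AnalysisError,
    BASELINE,
    DegenerateVarianceError,
    ParticipantModel,
    ParticipantSummary,
    apply_exclusion,
    build_experiment1_config,
    paired_test,
    paired_test_arrays,
    results_to_resultset,
    run_experiment,
    summarize_participant,
)


def summary(pid="P", frac_immediate=0.0, frac_delayed=0.0, means=None):
    means = means or {1.0: 0.0, 500.0: 0.0}
    return ParticipantSummary(
        participant_id=pid,
        raw_mean_ms=dict(means, **{BASELINE: 0.0}),
        baseline_mean_ms=0.0,
        corrected_mean_ms=dict(means),
        nonresponse_fraction={1.0: frac_immediate, 500.0: frac_delayed, BASELINE: 0.0},
    )


class TestExclusion:
    def test_fully_responding_participant_retained(self):
        retained, excluded = apply_exclusion([summary()])
        assert len(retained) == 1 and not excluded

    def test_threshold_is_strict_at_25_percent(self):
        at_boundary = summary("ok", frac_delayed=10 / 40)     # exactly 25%
        over = summary("out", frac_delayed=11 / 40)           # 27.5%
        retained, excluded = apply_exclusion([at_boundary, over])
        assert [s.participant_id for s in retained] == ["ok"]
        assert [s.participant_id for s in excluded] == ["out"]

    def test_either_condition_triggers_exclusion(self):
        retained, excluded = apply_exclusion([summary("a", frac_immediate=0.3),
                                              summary("b", frac_delayed=0.3)])
        assert not retained and len(excluded) == 2

    def test_engineered_cohort_drops_exactly_the_over_threshold_members(self):
        cohort = [summary(f"P{i}") for i in range(57)]
        cohort += [summary(f"X{i}", frac_immediate=0.5) for i in range(7)]
        retained, excluded = apply_exclusion(cohort)
        assert len(retained) == 57 and len(excluded) == 7


class TestSummarize:
    def test_noiseless_unbiased_participant_has_zero_means(self):
        cfg = build_experiment1_config(seed=1)
        model = ParticipantModel(bias_ms={}, judgment_sd_ms=0.0)
        results = run_experiment(cfg, model, master_seed=4)
        rs = results_to_resultset(results, cfg, "A", "P001", 4)
        s = summarize_participant(rs, cfg)
        assert s.raw_mean_ms[1.0] == pytest.approx(0.0, abs=1e-9)
        assert s.raw_mean_ms[500.0] == pytest.approx(0.0, abs=1e-9)
        assert s.baseline_mean_ms == pytest.approx(0.0, abs=1e-9)

    def test_corrected_mean_is_raw_minus_baseline(self):
        cfg = build_experiment1_config(seed=1)
        model = ParticipantModel(
            bias_ms={1.0: 50.0, 500.0: 90.0, BASELINE: 10.0}, judgment_sd_ms=0.0)
        results = run_experiment(cfg, model, master_seed=4)
        rs = results_to_resultset(results, cfg, "A", "P001", 4)
        s = summarize_participant(rs, cfg)
        assert s.corrected_mean_ms[1.0] == pytest.approx(40.0)
        assert s.corrected_mean_ms[500.0] == pytest.approx(80.0)
        for c in (1.0, 500.0):
            assert s.corrected_mean_ms[c] == pytest.approx(
                s.raw_mean_ms[c] - s.baseline_mean_ms)

    def test_missing_baseline_is_analysis_error(self):
        cfg = build_experiment1_config(seed=1)
        cfg.phases = cfg.phases[:1]  # drop the baseline phase
        model = ParticipantModel()
        results = run_experiment(cfg, model, master_seed=4)
        rs = results_to_resultset(results, cfg, "A", "P001", 4)
        with pytest.raises(AnalysisError, match="baseline"):
            summarize_participant(rs, cfg)

    def test_constant_shift_of_one_participant_leaves_corrected_means_unchanged(self):
        """Baseline subtraction removes any constant judgment offset."""
        cfg = build_experiment1_config(seed=1)
        model = ParticipantModel(bias_ms={1.0: 5.0, 500.0: 45.0, BASELINE: 0.0},
                                 judgment_sd_ms=10.0)
        results = run_experiment(cfg, model, master_seed=6)
        rs = results_to_resultset(results, cfg, "A", "P001", 6)
        shifted = copy.deepcopy(rs)
        for rec, judg in shifted.trials:
            if judg.judged_time_ms is not None:
                t = (judg.judged_time_ms + 123.0) % rec.cycle_ms
                judg.judged_time_ms = t
                judg.judged_angle_deg = t / rec.cycle_ms * 360.0
        s0 = summarize_participant(rs, cfg)
        s1 = summarize_participant(shifted, cfg)
        for c in (1.0, 500.0):
            assert s1.corrected_mean_ms[c] == pytest.approx(s0.corrected_mean_ms[c])
            assert s1.raw_mean_ms[c] == pytest.approx(s0.raw_mean_ms[c] + 123.0)


class TestPairedTest:
    def test_matches_hand_computed_fixture(self):
        """Differences {10,20,15,5,25}: mean 15, SD sqrt(62.5), t = 15/(SD/sqrt 5)."""
        diffs = [10.0, 20.0, 15.0, 5.0, 25.0]
        cohort = [summary(f"P{i}", means={1.0: 0.0, 500.0: d})
                  for i, d in enumerate(diffs)]
        r = paired_test(cohort, 500.0, 1.0, use_baseline=True)
        sd = math.sqrt(62.5)
        assert r.n == 5 and r.df == 4
        assert r.mean_diff == pytest.approx(15.0)
        assert r.t == pytest.approx(15.0 / (sd / math.sqrt(5)))
        assert r.d_z == pytest.approx(15.0 / sd)
        # cross-check p against the scipy implementation of the same test
        t_sp, p_sp = stats.ttest_rel([d for d in diffs], [0.0] * 5)
        assert r.t == pytest.approx(t_sp)
        assert r.p == pytest.approx(p_sp)

    def test_zero_variance_of_differences_is_degenerate(self):
        cohort = [summary(f"P{i}", means={1.0: 3.0, 500.0: 10.0}) for i in range(5)]
        with pytest.raises(DegenerateVarianceError):
            paired_test(cohort, 500.0, 1.0)

    def test_sem_definition(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(40, 10, 30), rng.normal(0, 10, 30)
        r = paired_test_arrays(a, b)
        assert r.sem_a == pytest.approx(np.std(a, ddof=1) / math.sqrt(30))
        assert r.df == 29

    def test_raw_and_corrected_paths_share_the_t_statistic(self):
        """The participant's own baseline cancels in the paired difference."""
        rng = np.random.default_rng(2)
        cohort = []
        for i in range(20):
            base = rng.normal(0, 30)
            imm, dly = rng.normal(5, 20), rng.normal(40, 20)
            cohort.append(ParticipantSummary(
                participant_id=f"P{i}",
                raw_mean_ms={1.0: imm, 500.0: dly, BASELINE: base},
                baseline_mean_ms=base,
                corrected_mean_ms={1.0: imm - base, 500.0: dly - base},
                nonresponse_fraction={1.0: 0.0, 500.0: 0.0, BASELINE: 0.0},
            ))
        r_corr = paired_test(cohort, 500.0, 1.0, use_baseline=True)
        r_raw = paired_test(cohort, 500.0, 1.0, use_baseline=False)
        assert r_corr.t == pytest.approx(r_raw.t)
        assert r_corr.mean_diff == pytest.approx(r_raw.mean_diff)
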