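"""Intentional-binding analysis pipeline: per-participant summaries,
non-response exclusion, baseline correction, and the paired comparison.

The dependent variable is the judgment error — the signed circular difference
between the judged and the actual press time on the dial.  Per participant,
errors are averaged within each feedback condition; the mean error on
no-feedback (baseline) trials is subtracted to remove the participant's
constant judgment offset.  Retained participants' per-condition means enter a
related-samples t-test; both d_z (mean difference over SD of differences) and
d_av (mean difference over the average condition SD) are reported, since
published effect sizes for this paradigm use either convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .config import BASELINE, ExperimentConfig
from .engine import wrapped_diff
from .records import ResultSet

__all__ = [
    "ParticipantSummary",
    "PairedTestResult",
    "AnalysisError",
    "DegenerateVarianceError",
    "summarize_participant",
    "apply_exclusion",
    "paired_test",
    "paired_test_arrays",
]

Condition = Union[float, str]


class AnalysisError(ValueError):
    """The analysis cannot be performed on the given data."""


class DegenerateVarianceError(AnalysisError):
    """The paired differences have zero variance; t is undefined."""


@dataclass
class ParticipantSummary:
    """Per-participant condition means, baseline, and response completeness."""

    participant_id: str
    raw_mean_ms: dict[Condition, float]
    baseline_mean_ms: float
    corrected_mean_ms: dict[Condition, float]
    nonresponse_fraction: dict[Condition, float]
    n_trials: dict[Condition, int] = field(default_factory=dict)


@dataclass
class PairedTestResult:
    """Related-samples t-test between two conditions with effect sizes."""

    n: int
    df: int
    condition_a: Condition
    condition_b: Condition
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    mean_diff: float
    sem_diff: float
    t: float
    p: float
    d_z: float
    d_av: float


def summarize_participant(results: ResultSet,
                          cfg: Optional[ExperimentConfig] = None) -> ParticipantSummary:
    """Reduce one participant's trials to per-condition judgment-error means.

    The error on each responded trial is ``wrapped_diff(judged, actual,
    cycle)``; condition membership comes from the configured tone delay on
    the trial record (absent delay = baseline).  Raises
    :class:`AnalysisError` when no responded baseline trial exists, because
    baseline correction is then impossible.
    """
    if cfg is not None:
        results.validate(expected_trials=cfg.total_trials)
    errors: dict[Condition, list[float]] = {}
    misses: dict[Condition, int] = {}
    totals: dict[Condition, int] = {}
    for rec, judg in results.trials:
        cond: Condition = BASELINE if rec.tone_ms is None else rec.tone_ms
        totals[cond] = totals.get(cond, 0) + 1
        if judg.judged_time_ms is None or judg.actual_event_ms is None:
            misses[cond] = misses.get(cond, 0) + 1
            continue
        err = wrapped_diff(judg.judged_time_ms, judg.actual_event_ms, rec.cycle_ms)
        errors.setdefault(cond, []).append(err)

    if BASELINE not in errors:
        raise AnalysisError(
            f"participant {results.participant_id}: no responded baseline trials; "
            "baseline correction impossible"
        )
    raw = {c: float(np.mean(v)) for c, v in errors.items()}
    baseline = raw[BASELINE]
    corrected = {c: m - baseline for c, m in raw.items() if c != BASELINE}
    frac = {c: misses.get(c, 0) / totals[c] for c in totals}
    return ParticipantSummary(
        participant_id=results.participant_id,
        raw_mean_ms=raw,
        baseline_mean_ms=baseline,
        corrected_mean_ms=corrected,
        nonresponse_fraction=frac,
        n_trials=totals,
    )


def apply_exclusion(summaries: Sequence[ParticipantSummary],
                    threshold: float = 0.25,
                    ) -> tuple[list[ParticipantSummary], list[ParticipantSummary]]:
    """Split a cohort on the non-response criterion.

    A participant is excluded iff their non-response fraction STRICTLY
    exceeds ``threshold`` in at least one feedback condition (baseline
    trials do not trigger exclusion).  10/40 missed (exactly 25%) is
    retained; 11/40 is excluded.
    """
    retained, excluded = [], []
    for s in summaries:
        over = any(f > threshold for c, f in s.nonresponse_fraction.items()
                   if c != BASELINE)
        (excluded if over else retained).append(s)
    return retained, excluded


def paired_test_arrays(a: np.ndarray, b: np.ndarray,
                       condition_a: Condition = "a",
                       condition_b: Condition = "b") -> PairedTestResult:
    """Related-samples t-test on two paired vectors of per-participant means."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError("paired test needs two equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise AnalysisError("paired test needs at least 2 participants")
    diffs = a - b
    sd_diff = float(np.std(diffs, ddof=1))
    if sd_diff == 0.0:
        raise DegenerateVarianceError("all paired differences are identical")
    mean_diff = float(np.mean(diffs))
    sem_diff = sd_diff / math.sqrt(n)
    t = mean_diff / sem_diff
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    d_av = mean_diff / ((sd_a + sd_b) / 2.0) if (sd_a + sd_b) > 0 else math.nan
    return PairedTestResult(
        n=n, df=df, condition_a=condition_a, condition_b=condition_b,
        mean_a=float(np.mean(a)), sem_a=sd_a / math.sqrt(n),
        mean_b=float(np.mean(b)), sem_b=sd_b / math.sqrt(n),
        mean_diff=mean_diff, sem_diff=sem_diff,
        t=t, p=p, d_z=mean_diff / sd_diff, d_av=d_av,
    )


def paired_test(retained: Sequence[ParticipantSummary],
                condition_a: Condition, condition_b: Condition,
                use_baseline: bool = True) -> PairedTestResult:
    """Paired comparison of two conditions across retained participants.

    With ``use_baseline=True`` the baseline-corrected per-participant means
    are compared (the headline analysis); otherwise the raw means (the
    robustness check).  Note the paired t is invariant to baseline
    subtraction itself — subtracting each participant's own constant cancels
    in the a-b difference — so the two paths differ only in the reported
    condition means.
    """
    if len(retained) < 2:
        raise AnalysisError("paired test needs at least 2 retained participants")
    source = "corrected_mean_ms" if use_baseline else "raw_mean_ms"
    try:
        a = np.array([getattr(s, source)[condition_a] for s in retained])
        b = np.array([getattr(s, source)[condition_b] for s in retained])
    except KeyError as exc:
        raise AnalysisError(f"condition {exc.args[0]!r} missing for some participant") from exc
    return paired_test_arrays(a, b, condition_a, condition_b)
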