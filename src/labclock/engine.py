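"""Deterministic trial engine: a discrete-event simulation of the rotating-clock
paradigm on a virtual clock.

Each trial follows the canonical sequence: a warning tone, a uniformly random
initial delay, two full rotations of the clock dot (the first is observation
only, a key press is accepted only during the second), an optional feedback
tone a configured delay after the accepted press, and a clock-position
judgment probe.  With jitter disabled every scheduled event executes exactly
on time, so measured durations equal configured ones; an optional Gaussian
per-event latency model stands in for browser/OS scheduling noise.

All trial-relative times are 0-based at rotation start; intervals are
half-open.  Geometry helpers convert between dial angles and times within a
rotation, and :func:`wrapped_diff` gives the signed circular difference used
for judgment errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .config import ExperimentConfig, TrialSpec, condition_of
from .records import JudgmentRecord, ResultSet, TrialRecord

__all__ = [
    "VirtualClock",
    "TrialOutcome",
    "sample_initial_delay",
    "scramble_trials",
    "angle_to_time",
    "time_to_angle",
    "wrapped_diff",
    "run_trial",
    "run_experiment",
]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class VirtualClock:
    """Monotonic virtual time with an optional per-event latency law.

    ``execute`` maps a scheduled time to an executed time: identical under
    zero jitter, otherwise shifted by a Gaussian(mean, sd) latency sample.
    Event streams may be concurrent (a feedback tone can sound while the dot
    is still rotating), so execution does not reorder events; ``now_ms`` — the
    furthest executed time — is non-decreasing.
    """

    now_ms: float = 0.0
    jitter_mean_ms: float = 0.0
    jitter_sd_ms: float = 0.0
    rng: Optional[np.random.Generator] = None

    def execute(self, scheduled_ms: float) -> float:
        executed = scheduled_ms
        if self.jitter_mean_ms != 0.0 or self.jitter_sd_ms != 0.0:
            rng = self.rng if self.rng is not None else np.random.default_rng()
            executed += self.jitter_mean_ms + self.jitter_sd_ms * rng.standard_normal()
        self.now_ms = max(executed, self.now_ms)
        return executed


@dataclass
class TrialOutcome:
    """A trial's record plus the engine's view of the accepted press.

    ``valid_press_ms`` is the accepted key press relative to rotation start
    (``None`` on non-response trials); when present it lies in
    ``[cycle_ms, 2*cycle_ms)`` — i.e. within the second rotation.
    """

    record: TrialRecord
    valid_press_ms: Optional[float]
    press_in_first_rotation: bool
    rotation_start_ms: float = 0.0

    @property
    def condition(self) -> Union[float, str]:
        from .config import BASELINE
        return BASELINE if self.record.tone_ms is None else self.record.tone_ms


def sample_initial_delay(min_ms: float, max_ms: float,
                         seed=None) -> float:
    """Draw the pre-rotation delay uniformly from ``[min_ms, max_ms]``.

    A degenerate interval (min == max) yields a constant delay.
    """
    if not (0 <= min_ms <= max_ms):
        raise ValueError(f"invalid delay range [{min_ms}, {max_ms}]")
    if min_ms == max_ms:
        return float(min_ms)
    rng = _as_rng(seed)
    return float(rng.uniform(min_ms, max_ms))


def scramble_trials(trials: Sequence[TrialSpec], seed=None) -> list[TrialSpec]:
    """Fisher–Yates shuffle of a trial list (seeded, input untouched).

    Implements the classic backward swap so every permutation is equally
    likely under the generator's uniform integers.
    """
    rng = _as_rng(seed)
    out = list(trials)
    for i in range(len(out) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        out[i], out[j] = out[j], out[i]
    return out


def angle_to_time(angle_deg, cycle_ms):
    """Convert a dial angle to time within one rotation (linear sweep).

    The dot moves at constant angular velocity, so ``time = angle/360 * cycle``.
    Angles outside [0, 360) are normalized modulo 360.
    """
    if np.any(np.asarray(cycle_ms) <= 0):
        raise ValueError("cycle_ms must be positive")
    angle = np.mod(angle_deg, 360.0)
    result = angle / 360.0 * cycle_ms
    return float(result) if np.isscalar(angle_deg) else result


def time_to_angle(time_ms, cycle_ms):
    """Inverse of :func:`angle_to_time`: dial angle in [0, 360) of a time."""
    if np.any(np.asarray(cycle_ms) <= 0):
        raise ValueError("cycle_ms must be positive")
    result = np.mod(time_ms, cycle_ms) / cycle_ms * 360.0
    return float(result) if np.isscalar(time_ms) else result


def wrapped_diff(judged_ms, actual_ms, cycle_ms):
    """Signed circular difference ``judged - actual`` in (-cycle/2, cycle/2].

    Shifts the plain difference by the integer multiple of the cycle that
    minimizes its magnitude; an exact half-cycle tie maps to ``+cycle/2``.
    Used for judgment errors on the circular dial, where a judgment just
    before 12 o'clock and a press just after differ by milliseconds, not by
    nearly a full rotation.
    """
    if np.any(np.asarray(cycle_ms) <= 0):
        raise ValueError("cycle_ms must be positive")
    d = np.mod(np.asarray(judged_ms, dtype=float) - actual_ms, cycle_ms)
    d = np.where(d > np.asarray(cycle_ms) / 2.0, d - cycle_ms, d)
    return float(d) if d.ndim == 0 else d


PressSource = Union[Sequence[float], Callable, "object"]


def _press_times(press_script: PressSource, spec: TrialSpec,
                 rng: np.random.Generator) -> list[float]:
    """Resolve scripted presses or a participant-model hook to press times
    relative to rotation start."""
    if press_script is None:
        return []
    if hasattr(press_script, "sample_press_times"):
        return list(press_script.sample_press_times(spec.cycle_ms, rng))
    if callable(press_script):
        return list(press_script(spec, rng))
    return [float(p) for p in press_script]


def run_trial(spec: TrialSpec, cfg: ExperimentConfig,
              press_script: PressSource,
              clock: Optional[VirtualClock] = None,
              seed=None) -> TrialOutcome:
    """Execute one trial on the virtual clock and log it.

    Event order: warning tone -> initial random delay -> rotation start ->
    two full rotations -> (feedback tone ``tone_delay_ms`` after the accepted
    press, if configured and a valid press occurred) -> trial end.

    The accepted press is the FIRST press during the second rotation
    (relative time in ``[cycle, 2*cycle)``); earlier or later presses are
    logged but never accepted.  A trial without a valid press is a legal
    non-response outcome.
    """
    rng = _as_rng(seed)
    if clock is None:
        clock = VirtualClock()
    t0 = clock.now_ms
    start_trial = t0
    start_audio_s = t0 / 1000.0
    warning_time = clock.execute(t0)

    delay = sample_initial_delay(cfg.random_delay_min_ms, cfg.random_delay_max_ms, rng)
    rot_start = clock.execute(warning_time + delay)
    rot_end = clock.execute(rot_start + 2.0 * spec.cycle_ms)
    cycle_time = rot_end - rot_start

    rel_presses = sorted(_press_times(press_script, spec, rng))
    abs_presses = [rot_start + p for p in rel_presses]
    accepted_rel = next((p for p in rel_presses
                         if spec.cycle_ms <= p < 2.0 * spec.cycle_ms), None)
    in_first = any(0.0 <= p < spec.cycle_ms for p in rel_presses)

    tone_time = None
    end_candidates = [rot_end] + abs_presses
    if accepted_rel is not None and spec.tone_delay_ms is not None:
        press_abs = rot_start + accepted_rel
        tone_exec = clock.execute(press_abs + spec.tone_delay_ms)
        tone_time = tone_exec - press_abs
        end_candidates.append(tone_exec)
    end_trial = clock.execute(max(end_candidates))

    record = TrialRecord(
        initial_random_time_ms=delay,
        cycle_ms=spec.cycle_ms,
        cycle_time_ms=cycle_time,
        tone_ms=spec.tone_delay_ms,
        tone_time_ms=tone_time,
        key_press_trial_times_ms=abs_presses,
        start_trial_time_ms=start_trial,
        end_trial_time_ms=end_trial,
        start_trial_audio_time_s=start_audio_s,
    )
    return TrialOutcome(record=record, valid_press_ms=accepted_rel,
                        press_in_first_rotation=in_first,
                        rotation_start_ms=rot_start)


def run_experiment(cfg: ExperimentConfig, participant,
                   master_seed: int,
                   clock: Optional[VirtualClock] = None,
                   ) -> list[tuple[TrialOutcome, JudgmentRecord]]:
    """Run all configured phases for one simulated participant.

    Phases execute in order; a phase with ``scramble=True`` is shuffled with
    a seed derived from ``master_seed``.  Each trial is followed by one
    judgment probe (skipped — an absent judgment — on non-response trials).
    The whole run is reproducible from ``master_seed``.
    """
    root = np.random.SeedSequence(master_seed)
    s_scramble, s_trials, s_participant = root.spawn(3)
    rng_scramble = np.random.default_rng(s_scramble)
    rng_trials = np.random.default_rng(s_trials)
    rng_participant = np.random.default_rng(s_participant)

    if hasattr(participant, "draw_participant"):
        participant = participant.draw_participant(rng_participant)

    if clock is None:
        clock = VirtualClock()
    if clock.rng is None:
        clock.rng = rng_trials

    results: list[tuple[TrialOutcome, JudgmentRecord]] = []
    for phase in cfg.phases:
        trials = phase.trials
        if phase.scramble:
            trials = scramble_trials(trials, rng_scramble)
        for spec in trials:
            outcome = run_trial(spec, cfg, participant, clock, rng_trials)
            if hasattr(participant, "make_judgment"):
                judgment = participant.make_judgment(outcome, condition_of(spec),
                                                     rng_participant)
            else:
                judgment = JudgmentRecord(probe="action",
                                          actual_event_ms=outcome.valid_press_ms)
            results.append((outcome, judgment))
    return results


def results_to_resultset(results: list[tuple[TrialOutcome, JudgmentRecord]],
                         cfg: ExperimentConfig, group_id: str,
                         participant_id: str, master_seed: int) -> ResultSet:
    """Package an experiment run as a serializable result set."""
    return ResultSet(
        code=cfg.code, group_id=group_id, participant_id=participant_id,
        trials=[(o.record, j) for o, j in results],
        engine_seed=int(master_seed),
    )
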