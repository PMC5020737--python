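"""Generative model of participant behavior: press times and biased
clock-position judgments.

The model is deliberately the simplest structure consistent with a
condition-means analysis: a participant presses at a uniformly random moment
of the second rotation, and their judged press time is the true press time
plus a constant personal offset, plus a condition-dependent bias (the
temporal-binding shift toward the feedback tone), plus Gaussian trial noise —
all wrapped onto the circular dial.  Misses (no press during the second
rotation) occur with a fixed probability per trial.

Presets emulate the statistical structure of the two published experiments:
an in-lab cohort with raw condition means of 3.806 ms (immediate, 1 ms
feedback) and 41.152 ms (delayed, 500 ms feedback) at n = 57, and an online
cohort with raw means of -32.967 and 0.041 ms at n = 52 — the online
immediate-feedback judgments sit *before* the actual press, consistent with
participants expecting web feedback to lag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .config import BASELINE
from .engine import time_to_angle, angle_to_time, wrapped_diff, TrialOutcome
from .records import JudgmentRecord

__all__ = [
    "ParticipantModel",
    "UnknownConditionError",
    "generate_judgment",
    "build_experiment_preset",
    "simulate_cohort_mean_errors",
]

Condition = Union[float, str]


class UnknownConditionError(KeyError):
    """A judgment was requested for a condition the model does not configure."""


@dataclass
class ParticipantModel:
    """Generative parameters for one participant (or a population of them).

    Parameters
    ----------
    press_min_ms, press_max_ms
        Uniform press-time window within the second rotation, relative to
        that rotation's start.  ``press_max_ms=None`` means ``cycle - 200``,
        keeping presses away from the dial-wrap edges.
    bias_ms
        Mean judgment shift per condition (key: configured tone delay in ms,
        or ``BASELINE``).  An empty map means unbiased in every condition.
    bias_between_sd_ms
        Between-participant SD of each condition bias; used when drawing an
        individual from the population, zero for a concrete individual.
    judgment_sd_ms
        Within-participant Gaussian trial noise of the judgment.
    baseline_offset_mean_ms, baseline_offset_sd_ms
        Population law of the per-participant constant judgment offset; for
        a concrete individual the mean holds their drawn offset and the SD
        is zero.
    miss_prob
        Probability of a non-response trial.
    probe
        Which event is probed: ``action`` (judged press time), ``will``, or
        ``tone``.
    reference_n
        Cohort size the preset calibration refers to (informational).
    """

    press_min_ms: float = 200.0
    press_max_ms: Optional[float] = None
    bias_ms: dict[Condition, float] = field(default_factory=dict)
    bias_between_sd_ms: dict[Condition, float] = field(default_factory=dict)
    judgment_sd_ms: float = 20.0
    baseline_offset_mean_ms: float = 0.0
    baseline_offset_sd_ms: float = 0.0
    miss_prob: float = 0.0
    probe: str = "action"
    reference_n: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ValueError("miss_prob must be in [0, 1]")
        if self.judgment_sd_ms < 0:
            raise ValueError("judgment_sd_ms must be non-negative")

    # -- hooks used by the engine -------------------------------------------------

    def sample_press_times(self, cycle_ms: float, rng: np.random.Generator) -> list[float]:
        """Press times relative to rotation start; empty list on a miss."""
        if self.miss_prob > 0 and rng.random() < self.miss_prob:
            return []
        hi = self.press_max_ms if self.press_max_ms is not None else cycle_ms - 200.0
        if not (0.0 <= self.press_min_ms <= hi < cycle_ms):
            raise ValueError(f"press window [{self.press_min_ms}, {hi}] "
                             f"not within [0, {cycle_ms})")
        return [cycle_ms + float(rng.uniform(self.press_min_ms, hi))]

    def make_judgment(self, outcome: TrialOutcome, condition: Condition,
                      rng: np.random.Generator) -> JudgmentRecord:
        return generate_judgment(self, outcome, condition, rng)

    # -- population sampling ------------------------------------------------------

    def bias_for(self, condition: Condition) -> float:
        if not self.bias_ms:
            return 0.0
        try:
            return self.bias_ms[condition]
        except KeyError:
            raise UnknownConditionError(condition) from None

    def draw_participant(self, rng: np.random.Generator) -> "ParticipantModel":
        """Realize one individual from the population-level parameters."""
        offset = self.baseline_offset_mean_ms
        if self.baseline_offset_sd_ms > 0:
            offset += self.baseline_offset_sd_ms * rng.standard_normal()
        biases = dict(self.bias_ms)
        for cond, sd in self.bias_between_sd_ms.items():
            if sd > 0:
                biases[cond] = biases.get(cond, 0.0) + sd * rng.standard_normal()
        return replace(self, bias_ms=biases, bias_between_sd_ms={},
                       baseline_offset_mean_ms=offset, baseline_offset_sd_ms=0.0)

    # -- (de)serialization for CLI model files ------------------------------------

    def to_json(self) -> str:
        def enc_map(m):
            return {str(k): v for k, v in m.items()}
        doc = {
            "press_min_ms": self.press_min_ms, "press_max_ms": self.press_max_ms,
            "bias_ms": enc_map(self.bias_ms),
            "bias_between_sd_ms": enc_map(self.bias_between_sd_ms),
            "judgment_sd_ms": self.judgment_sd_ms,
            "baseline_offset_mean_ms": self.baseline_offset_mean_ms,
            "baseline_offset_sd_ms": self.baseline_offset_sd_ms,
            "miss_prob": self.miss_prob, "probe": self.probe,
            "reference_n": self.reference_n,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParticipantModel":
        doc = json.loads(text)

        def dec_key(k: str) -> Condition:
            try:
                return float(k)
            except ValueError:
                return k

        for name in ("bias_ms", "bias_between_sd_ms"):
            if name in doc:
                doc[name] = {dec_key(k): v for k, v in doc[name].items()}
        return cls(**doc)


def generate_judgment(model: ParticipantModel, outcome: TrialOutcome,
                      condition: Condition, seed=None) -> JudgmentRecord:
    """Produce a clock-position judgment for one trial outcome.

    The judged time is ``actual_event + personal_offset + bias[condition] +
    N(0, judgment_sd)`` wrapped onto the dial; the record stores both the
    dial angle and its time conversion.  Non-response trials yield an
    all-absent judgment record.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if outcome.valid_press_ms is None:
        return JudgmentRecord(probe=model.probe)

    press = outcome.valid_press_ms
    if model.probe == "tone" and outcome.record.tone_time_ms is not None:
        actual = press + outcome.record.tone_time_ms
    else:
        # 'will' has no separate generative law here; it is probed at the press
        actual = press

    bias = model.bias_for(condition)
    noise = model.judgment_sd_ms * rng.standard_normal() if model.judgment_sd_ms > 0 else 0.0
    judged = actual + model.baseline_offset_mean_ms + bias + noise

    cycle = outcome.record.cycle_ms
    angle = time_to_angle(judged, cycle)
    return JudgmentRecord(probe=model.probe,
                          judged_angle_deg=angle,
                          judged_time_ms=angle_to_time(angle, cycle),
                          actual_event_ms=actual)


# Calibration constants: raw per-condition mean judgments (ms) and SEMs
# printed for the two cohorts, and the retained cohort sizes.
_PRESETS = {
    "lab": dict(n=57, means={1.0: 3.806, 500.0: 41.152}, sems={1.0: 6.136, 500.0: 12.936}),
    "online": dict(n=52, means={1.0: -32.967, 500.0: 0.041}, sems={1.0: 7.786, 500.0: 15.868}),
}


def build_experiment_preset(which: str) -> ParticipantModel:
    """Population model calibrated to one of the two published cohorts.

    ``which`` is ``"lab"`` (in-laboratory cohort, n = 57) or ``"online"``
    (internet cohort, n = 52).  Condition bias means equal the printed raw
    condition means; the between-participant SD of each condition bias is
    ``SEM * sqrt(n)`` so the cohort SEM at the printed n matches the printed
    value.  The baseline bias is 0 (no feedback, no binding shift) with the
    immediate-condition between-participant SD; the within-trial judgment SD
    is a free parameter (20 ms) — the source reports no trial-level
    variability.
    """
    try:
        p = _PRESETS[which]
    except KeyError:
        raise ValueError(f"unknown preset {which!r} (expected 'lab' or 'online')") from None
    n = p["n"]
    bias = dict(p["means"])
    bias[BASELINE] = 0.0
    sds = {cond: sem * math.sqrt(n) for cond, sem in p["sems"].items()}
    sds[BASELINE] = min(sds.values())
    return ParticipantModel(bias_ms=bias, bias_between_sd_ms=sds,
                            judgment_sd_ms=20.0, miss_prob=0.02,
                            reference_n=n)


def simulate_cohort_mean_errors(model: ParticipantModel, n_participants: int,
                                n_trials: int, conditions: list[Condition],
                                rng: np.random.Generator,
                                cycle_ms: float = 2560.0) -> np.ndarray:
    """Vectorized per-participant mean judgment errors, one column per condition.

    Draws each participant's offset and condition biases from the population
    law, adds trial-level Gaussian noise, wraps every trial error onto the
    dial, and averages over trials — the same statistical pipeline the full
    engine produces, without discrete-event bookkeeping.  Used for large
    Monte-Carlo studies (e.g. null-calibration of the paired test).
    """
    k = len(conditions)
    offsets = (model.baseline_offset_mean_ms
               + model.baseline_offset_sd_ms * rng.standard_normal(n_participants))
    bias = np.array([model.bias_for(c) for c in conditions])
    bsd = np.array([model.bias_between_sd_ms.get(c, 0.0) for c in conditions])
    indiv_bias = bias + bsd * rng.standard_normal((n_participants, k))
    noise = model.judgment_sd_ms * rng.standard_normal((n_participants, k, n_trials))
    errors = offsets[:, None, None] + indiv_bias[:, :, None] + noise
    errors = wrapped_diff(errors, 0.0, cycle_ms)
    return errors.mean(axis=2)
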