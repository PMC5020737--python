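import json

import numpy as np
import pytest

from labclock import (
    ExperimentConfig,
    JudgmentRecord,
    ResultSet,
    TrialRecord,
    build_experiment1_config,
)


def make_group_doc(**overrides):
    """A minimal valid file-level (camelCase) group configuration object."""
    doc = {
        "code": "demo",
        "password": "1234",
        "randomDelayMin": 1000,
        "randomDelayMax": 3000,
        "postResultsURL": "https://example.org/results",
        "responseKey": "space",
        "sounds": {"getReady": "ready.wav", "frequency": 1000, "duration": 200},
        "messages": {"press": "Press the key during the second rotation"},
        "preScreens": [{"title": "Welcome", "content": "Hello"}],
        "passwordScreen": {"title": "Password", "content": "Enter the passcode"},
        "phases": [
            {
                "description": "training",
                "progress": True,
                "scramble": True,
                "trials": [{"cycle": 2560, "tone": 1}, {"cycle": 2560, "tone": 500}],
                "screen": {"title": "Done", "content": "Phase over"},
            }
        ],
        "postScreens": [{"title": "Bye", "content": "Thanks"}],
    }
    doc.update(overrides)
    return doc


def make_config_text(group_id="A", **overrides) -> str:
    return json.dumps({group_id: make_group_doc(**overrides)})


@pytest.fixture
def exp1_config() -> ExperimentConfig:
    return build_experiment1_config(1)


def random_resultset(rng: np.random.Generator, n_trials=None) -> ResultSet:
    """Randomized but invariant-respecting result set for round-trip tests."""
    if n_trials is None:
        n_trials = int(rng.integers(1, 8))
    trials = []
    t = 0.0
    for _ in range(n_trials):
        cycle = float(rng.choice([1280.0, 2560.0]))
        delay = float(rng.uniform(1000, 3000))
        start = t
        rot_start = start + delay
        has_tone = bool(rng.random() < 0.7)
        responded = bool(rng.random() < 0.85)
        presses, tone_ms, tone_time, judged_angle = [], None, None, None
        judged_time, actual = None, None
        end = rot_start + 2 * cycle
        if has_tone:
            tone_ms = float(rng.choice([1.0, 500.0]))
        if responded:
            rel = float(rng.uniform(cycle + 100, 2 * cycle - 100))
            presses = [rot_start + rel]
            if rng.random() < 0.3:  # an ignored first-rotation press
                presses.insert(0, rot_start + float(rng.uniform(0, cycle)))
            if has_tone:
                tone_time = tone_ms
                end = max(end, presses[-1] + tone_time)
            actual = rel
            judged_angle = float(rng.uniform(0, 360))
            judged_time = judged_angle / 360.0 * cycle
        rec = TrialRecord(
            initial_random_time_ms=delay, cycle_ms=cycle, cycle_time_ms=2 * cycle,
            tone_ms=tone_ms, tone_time_ms=tone_time,
            key_press_trial_times_ms=presses,
            start_trial_time_ms=start, end_trial_time_ms=end,
            start_trial_audio_time_s=start / 1000.0,
        )
        judg = JudgmentRecord(probe="action", judged_angle_deg=judged_angle,
                              judged_time_ms=judged_time, actual_event_ms=actual)
        trials.append((rec, judg))
        t = end
    return ResultSet(code="demo", group_id="A",
                     participant_id=f"P{int(rng.integers(1, 999)):03d}",
                     trials=trials, engine_seed=int(rng.integers(0, 2**31)))
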