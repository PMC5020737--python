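"""Experiment configuration: parsing, validation, defaults, and group assignment.

Configuration files are JSON documents whose top-level object maps a group
identifier (e.g. ``"A"``) to that group's full configuration.  File-level key
names are camelCase (``randomDelayMin``, ``postResultsURL`` ...) for
compatibility with Labclock Web configuration files; the in-memory model uses
normalized snake_case names with explicit units.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from typing import IO, Any, Iterator, Optional

import numpy as np
import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BASELINE",
    "Screen",
    "SoundConfig",
    "TrialSpec",
    "PhaseConfig",
    "ExperimentConfig",
    "ConfigSet",
    "ConfigValidationError",
    "GroupLookupError",
    "load_config",
    "dump_config",
    "assign_group",
    "build_experiment1_config",
    "condition_of",
]

#: Condition label for trials with no feedback tone configured.
BASELINE = "baseline"

#: Conventional rotation period of the clock dot, in milliseconds.
DEFAULT_CYCLE_MS = 2560.0


class ConfigValidationError(ValueError):
    """A configuration document failed validation.

    ``path`` names the offending location using the file-level (camelCase)
    key names, e.g. ``"A.phases"`` or ``"A.randomDelayMin"``.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class GroupLookupError(KeyError):
    """A requested group id does not exist in the configuration."""


class _Model(BaseModel):
    model_config = ConfigDict(populate_by_name=True, extra="allow")


class Screen(_Model):
    """A titled text screen shown to participants (content is never rendered here)."""

    title: str
    content: str


class SoundConfig(_Model):
    """Sounds used in an experiment.

    The get-ready warning is an audio file reference (opaque path); the
    feedback tone is procedurally generated from a frequency and duration.
    """

    get_ready: str = Field(alias="getReady")
    feedback_frequency_hz: float = Field(alias="frequency", gt=0)
    feedback_duration_ms: float = Field(alias="duration", gt=0)


class TrialSpec(_Model):
    """A planned trial: rotation period and optional feedback-tone delay.

    ``tone_delay_ms is None`` means no feedback tone on that trial — a
    distinct state from a zero delay.
    """

    cycle_ms: float = Field(alias="cycle", default=DEFAULT_CYCLE_MS, gt=0)
    tone_delay_ms: Optional[float] = Field(alias="tone", default=None, ge=0)


class PhaseConfig(_Model):
    """One experimental phase: a trial list plus per-phase presentation flags."""

    description: str
    progress: bool = False
    scramble: bool = False
    trials: list[TrialSpec] = Field(min_length=1)
    screen: Screen


class ExperimentConfig(_Model):
    """Full configuration of one experimental group."""

    code: str = Field(min_length=1)
    password: str
    random_delay_min_ms: float = Field(alias="randomDelayMin", ge=0)
    random_delay_max_ms: float = Field(alias="randomDelayMax", ge=0)
    post_results_url: str = Field(alias="postResultsURL")
    response_key: str = Field(alias="responseKey")
    sounds: SoundConfig
    messages: dict[str, str]
    pre_screens: list[Screen] = Field(alias="preScreens")
    password_screen: Screen = Field(alias="passwordScreen")
    phases: list[PhaseConfig] = Field(min_length=1)
    post_screens: list[Screen] = Field(alias="postScreens")

    @model_validator(mode="after")
    def _check_delay_range(self) -> "ExperimentConfig":
        if self.random_delay_min_ms > self.random_delay_max_ms:
            raise ValueError(
                "randomDelayMin must not exceed randomDelayMax "
                f"({self.random_delay_min_ms} > {self.random_delay_max_ms})"
            )
        return self

    @property
    def total_trials(self) -> int:
        return sum(len(p.trials) for p in self.phases)


class ConfigSet(Mapping):
    """Mapping of group id -> :class:`ExperimentConfig`, with parse warnings.

    ``warnings`` lists unknown fields that were preserved but are not part of
    the documented schema.
    """

    def __init__(self, groups: dict[str, ExperimentConfig], warnings: list[str]):
        self._groups = dict(groups)
        self.warnings = list(warnings)

    def __getitem__(self, key: str) -> ExperimentConfig:
        return self._groups[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._groups)

    def __len__(self) -> int:
        return len(self._groups)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ConfigSet(groups={sorted(self._groups)}, warnings={len(self.warnings)})"


def _collect_extra_warnings(model: BaseModel, path: str, warnings: list[str]) -> None:
    extra = model.model_extra or {}
    for key in extra:
        warnings.append(f"{path}.{key}: unknown field preserved")
    for name, value in model:
        if isinstance(value, BaseModel):
            _collect_extra_warnings(value, f"{path}.{name}", warnings)
        elif isinstance(value, list):
            for i, item in enumerate(value):
                if isinstance(item, BaseModel):
                    _collect_extra_warnings(item, f"{path}.{name}[{i}]", warnings)


def _error_path(group_id: str, exc: pydantic.ValidationError) -> str:
    err = exc.errors()[0]
    loc = [str(part) for part in err["loc"]]
    return ".".join([group_id, *loc]) if loc else group_id


def load_config(source: str | bytes | IO[str]) -> ConfigSet:
    """Parse and validate an experiment-configuration document.

    Parameters
    ----------
    source
        JSON text, bytes, or a readable text stream.  The top-level value
        must be an object mapping group ids to group-configuration objects.

    Returns
    -------
    ConfigSet
        Mapping of group id to validated :class:`ExperimentConfig`; unknown
        fields are preserved on the models and flagged in ``.warnings``.

    Raises
    ------
    ConfigValidationError
        On any schema violation, naming the JSON path of the first error.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigValidationError("$", f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigValidationError("$", "top-level value must be an object of groups")
    if not doc:
        raise ConfigValidationError("$", "no groups defined")

    groups: dict[str, ExperimentConfig] = {}
    warnings: list[str] = []
    for group_id, body in doc.items():
        if not isinstance(body, dict):
            raise ConfigValidationError(group_id, "group configuration must be an object")
        try:
            cfg = ExperimentConfig.model_validate(body)
        except pydantic.ValidationError as exc:
            err = exc.errors()[0]
            raise ConfigValidationError(_error_path(group_id, exc), err["msg"]) from exc
        groups[group_id] = cfg
        _collect_extra_warnings(cfg, group_id, warnings)
    return ConfigSet(groups, warnings)


def dump_config(configs: Mapping[str, ExperimentConfig], *, indent: int = 2) -> str:
    """Serialize configurations back to the camelCase JSON file format.

    Round-trips with :func:`load_config`: absent tone delays are omitted
    (never written as 0 or null) and preserved unknown fields are emitted.
    """
    doc = {
        gid: cfg.model_dump(by_alias=True, exclude_none=True)
        for gid, cfg in configs.items()
    }
    return json.dumps(doc, indent=indent, ensure_ascii=False)


def assign_group(
    configs: Mapping[str, ExperimentConfig],
    select_random: bool,
    requested: Optional[str] = None,
    seed: Optional[int] = None,
) -> str:
    """Assign a participant to a group, manually or pseudo-randomly.

    With ``select_random=False`` the ``requested`` id is returned after an
    existence check.  With ``select_random=True`` a group is drawn uniformly
    (independently per participant, not counterbalanced), reproducibly for a
    given ``seed``.
    """
    if not configs:
        raise GroupLookupError("no groups configured")
    if not select_random:
        if requested is None or requested not in configs:
            raise GroupLookupError(requested)
        return requested
    rng = np.random.default_rng(seed)
    keys = sorted(configs)
    return keys[int(rng.integers(len(keys)))]


def condition_of(trial: TrialSpec) -> float | str:
    """Condition label of a trial: its configured tone delay, or ``BASELINE``."""
    return BASELINE if trial.tone_delay_ms is None else trial.tone_delay_ms


def _default_screen(title: str) -> Screen:
    return Screen(title=title, content=title)


def build_experiment1_config(seed: int) -> ExperimentConfig:
    """Configuration replicating the within-subject feedback-delay design.

    A training phase of 80 trials — 40 with immediate (1 ms) and 40 with
    delayed (500 ms) feedback — in a seeded pseudorandom order fixed at build
    time (the "predefined pseudorandom sequence"), followed by a baseline
    phase of 20 trials with no feedback tone.  All rotation periods are
    2560 ms.  Distinct seeds yield distinct training sequences.
    """
    from .engine import scramble_trials  # local import: engine depends on config

    training = [TrialSpec(cycle_ms=DEFAULT_CYCLE_MS, tone_delay_ms=1.0) for _ in range(40)]
    training += [TrialSpec(cycle_ms=DEFAULT_CYCLE_MS, tone_delay_ms=500.0) for _ in range(40)]
    training = scramble_trials(training, seed=seed)
    baseline = [TrialSpec(cycle_ms=DEFAULT_CYCLE_MS) for _ in range(20)]
    return ExperimentConfig(
        code="experiment1",
        password="",
        random_delay_min_ms=1000.0,
        random_delay_max_ms=3000.0,
        post_results_url="",
        response_key="space",
        sounds=SoundConfig(get_ready="get_ready.wav",
                           feedback_frequency_hz=1000.0,
                           feedback_duration_ms=200.0),
        messages={},
        pre_screens=[_default_screen("Welcome")],
        password_screen=_default_screen("Password"),
        phases=[
            PhaseConfig(description="training (immediate vs delayed feedback, predefined order)",
                        progress=True, scramble=False, trials=training,
                        screen=_default_screen("End of training")),
            PhaseConfig(description="baseline (no feedback)",
                        progress=True, scramble=False, trials=baseline,
                        screen=_default_screen("End of experiment")),
        ],
        post_screens=[_default_screen("Thank you")],
    )
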