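"""Trial records and result sets: the per-trial log format, serialization, and
the local-backup / results-payload semantics.

A :class:`TrialRecord` mirrors the variables stored for every trial by the
original web tool: configured vs measured rotation and tone timings, all key
presses, and trial start/end timestamps.  Note the mixed units — everything is
in milliseconds except ``start_trial_audio_time_s``, which is a seconds
timestamp from the audio clock.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from typing import IO, Optional

__all__ = [
    "SCHEMA_VERSION",
    "TrialRecord",
    "JudgmentRecord",
    "ResultSet",
    "RecordInvariantError",
    "ResultParseError",
    "write_results",
    "read_results",
    "backup_and_payload",
]

SCHEMA_VERSION = 1

#: Table column order for CSV output: per-set metadata, then the stored
#: per-trial variables under their original names, then judgment columns.
_META_COLUMNS = ["ExperimentCode", "Group", "Participant", "Seed", "SchemaVersion"]
_TRIAL_COLUMNS = [
    "InitialRandomTime", "Cycle", "CycleTime", "Tone", "ToneTime",
    "KeyPressTrialTimes", "StartTrialTime", "EndTrialTime", "StartTrialAudioTime",
]
_JUDGMENT_COLUMNS = ["Probe", "JudgedAngle", "JudgedTime", "ActualEvent"]
_COLUMNS = _META_COLUMNS + _TRIAL_COLUMNS + _JUDGMENT_COLUMNS


class RecordInvariantError(ValueError):
    """A record violates a structural invariant (e.g. end before start)."""


class ResultParseError(ValueError):
    """A result stream could not be parsed; names the line and field."""

    def __init__(self, line: int, field_name: str, message: str):
        self.line = line
        self.field_name = field_name
        super().__init__(f"line {line}, field {field_name!r}: {message}")


@dataclass
class TrialRecord:
    """One executed trial's log.

    ``tone_ms`` is the configured feedback delay (``None`` = no feedback
    configured); ``tone_time_ms`` is the measured press-to-tone delay
    (``None`` when no tone was presented).
    """

    initial_random_time_ms: float
    cycle_ms: float
    cycle_time_ms: float
    tone_ms: Optional[float]
    tone_time_ms: Optional[float]
    key_press_trial_times_ms: list[float]
    start_trial_time_ms: float
    end_trial_time_ms: float
    start_trial_audio_time_s: float

    def validate(self) -> None:
        if self.end_trial_time_ms < self.start_trial_time_ms:
            raise RecordInvariantError(
                f"end_trial_time_ms ({self.end_trial_time_ms}) precedes "
                f"start_trial_time_ms ({self.start_trial_time_ms})"
            )
        for p in self.key_press_trial_times_ms:
            if not (self.start_trial_time_ms <= p <= self.end_trial_time_ms):
                raise RecordInvariantError(
                    f"key press at {p} outside trial interval "
                    f"[{self.start_trial_time_ms}, {self.end_trial_time_ms}]"
                )
        if self.tone_time_ms is not None:
            if self.tone_ms is None:
                raise RecordInvariantError("tone_time_ms present without configured tone_ms")
            if not self.key_press_trial_times_ms:
                raise RecordInvariantError("tone_time_ms present without any key press")


@dataclass
class JudgmentRecord:
    """A clock-position judgment for one probed event on one trial.

    ``judged_angle_deg`` is the dial position reported by the participant;
    ``judged_time_ms`` is its conversion to time within one rotation.  Both
    are ``None`` on non-response trials.  ``actual_event_ms`` is the true
    time of the probed event relative to rotation start.
    """

    probe: str = "action"
    judged_angle_deg: Optional[float] = None
    judged_time_ms: Optional[float] = None
    actual_event_ms: Optional[float] = None

    def validate(self) -> None:
        if (self.judged_angle_deg is None) != (self.judged_time_ms is None):
            raise RecordInvariantError(
                "judged_time_ms must be present exactly when judged_angle_deg is"
            )
        if self.probe not in ("action", "will", "tone"):
            raise RecordInvariantError(f"unknown probe {self.probe!r}")


@dataclass
class ResultSet:
    """All results of one participant in one group."""

    code: str
    group_id: str
    participant_id: str
    trials: list[tuple[TrialRecord, JudgmentRecord]]
    engine_seed: int
    schema_version: int = SCHEMA_VERSION

    def validate(self, expected_trials: Optional[int] = None) -> None:
        for rec, judg in self.trials:
            rec.validate()
            judg.validate()
        if expected_trials is not None and len(self.trials) != expected_trials:
            raise RecordInvariantError(
                f"trial count {len(self.trials)} != configured total {expected_trials}"
            )


def _fmt(value: Optional[float]) -> str:
    # repr round-trips floats exactly; ABSENT -> empty field
    if value is None:
        return ""
    return repr(float(value))


def _parse_float(text: str, line: int, name: str, required: bool = True) -> Optional[float]:
    if text == "":
        if required:
            raise ResultParseError(line, name, "required value missing")
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ResultParseError(line, name, f"not a number: {text!r}") from exc


def _trial_to_row(rs: ResultSet, rec: TrialRecord, judg: JudgmentRecord) -> list[str]:
    presses = ",".join(repr(float(p)) for p in rec.key_press_trial_times_ms)
    return [
        rs.code, rs.group_id, rs.participant_id, str(rs.engine_seed), str(rs.schema_version),
        _fmt(rec.initial_random_time_ms), _fmt(rec.cycle_ms), _fmt(rec.cycle_time_ms),
        _fmt(rec.tone_ms), _fmt(rec.tone_time_ms), presses,
        _fmt(rec.start_trial_time_ms), _fmt(rec.end_trial_time_ms),
        repr(float(rec.start_trial_audio_time_s)),
        judg.probe, _fmt(judg.judged_angle_deg), _fmt(judg.judged_time_ms),
        _fmt(judg.actual_event_ms),
    ]


def _trial_to_obj(rec: TrialRecord, judg: JudgmentRecord) -> dict:
    return {"type": "trial", "record": asdict(rec), "judgment": asdict(judg)}


def write_results(rs: ResultSet, format: str = "csv") -> bytes:
    """Serialize a result set to CSV or JSON-lines (UTF-8 bytes).

    CSV uses RFC-4180 quoting with every field quoted, one row per trial; the
    key-press list is a comma-joined field.  Absent values are empty CSV
    fields / JSON nulls.
    """
    rs.validate()
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, quoting=csv.QUOTE_ALL, lineterminator="\r\n")
        writer.writerow(_COLUMNS)
        for rec, judg in rs.trials:
            writer.writerow(_trial_to_row(rs, rec, judg))
        return buf.getvalue().encode("utf-8")
    if format == "jsonl":
        header = {
            "type": "header", "code": rs.code, "group_id": rs.group_id,
            "participant_id": rs.participant_id, "engine_seed": rs.engine_seed,
            "schema_version": rs.schema_version,
        }
        lines = [json.dumps(header)]
        lines += [json.dumps(_trial_to_obj(rec, judg)) for rec, judg in rs.trials]
        return ("\n".join(lines) + "\n").encode("utf-8")
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")


def _record_from_fields(fields: dict[str, str], line: int) -> tuple[TrialRecord, JudgmentRecord]:
    press_text = fields["KeyPressTrialTimes"]
    presses = []
    if press_text:
        for part in press_text.split(","):
            presses.append(_parse_float(part, line, "KeyPressTrialTimes"))
    rec = TrialRecord(
        initial_random_time_ms=_parse_float(fields["InitialRandomTime"], line, "InitialRandomTime"),
        cycle_ms=_parse_float(fields["Cycle"], line, "Cycle"),
        cycle_time_ms=_parse_float(fields["CycleTime"], line, "CycleTime"),
        tone_ms=_parse_float(fields["Tone"], line, "Tone", required=False),
        tone_time_ms=_parse_float(fields["ToneTime"], line, "ToneTime", required=False),
        key_press_trial_times_ms=presses,
        start_trial_time_ms=_parse_float(fields["StartTrialTime"], line, "StartTrialTime"),
        end_trial_time_ms=_parse_float(fields["EndTrialTime"], line, "EndTrialTime"),
        start_trial_audio_time_s=_parse_float(fields["StartTrialAudioTime"], line, "StartTrialAudioTime"),
    )
    judg = JudgmentRecord(
        probe=fields["Probe"] or "action",
        judged_angle_deg=_parse_float(fields["JudgedAngle"], line, "JudgedAngle", required=False),
        judged_time_ms=_parse_float(fields["JudgedTime"], line, "JudgedTime", required=False),
        actual_event_ms=_parse_float(fields["ActualEvent"], line, "ActualEvent", required=False),
    )
    try:
        rec.validate()
        judg.validate()
    except RecordInvariantError as exc:
        raise ResultParseError(line, "record", str(exc)) from exc
    return rec, judg


def _read_csv(text: str) -> ResultSet:
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or rows[0] != _COLUMNS:
        raise ResultParseError(1, "header", "missing or unexpected column header")
    meta = None
    trials = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(_COLUMNS):
            raise ResultParseError(i, "row", f"expected {len(_COLUMNS)} fields, got {len(row)}")
        fields = dict(zip(_COLUMNS, row))
        row_meta = tuple(fields[c] for c in _META_COLUMNS)
        if meta is None:
            meta = row_meta
        elif row_meta != meta:
            raise ResultParseError(i, "metadata", "inconsistent result-set metadata across rows")
        trials.append(_record_from_fields(fields, i))
    if meta is None:
        raise ResultParseError(2, "row", "result set contains no trials")
    code, group, participant, seed, version = meta
    return ResultSet(code=code, group_id=group, participant_id=participant,
                     trials=trials, engine_seed=int(seed), schema_version=int(version))


def _read_jsonl(text: str) -> ResultSet:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ResultParseError(1, "header", "empty stream")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise ResultParseError(1, "header", f"invalid JSON: {exc}") from exc
    if header.get("type") != "header":
        raise ResultParseError(1, "header", "first line must be the header object")
    trials = []
    for i, ln in enumerate(lines[1:], start=2):
        try:
            obj = json.loads(ln)
        except json.JSONDecodeError as exc:
            raise ResultParseError(i, "row", f"invalid JSON: {exc}") from exc
        rec = TrialRecord(**obj["record"])
        judg = JudgmentRecord(**obj["judgment"])
        try:
            rec.validate()
            judg.validate()
        except RecordInvariantError as exc:
            raise ResultParseError(i, "record", str(exc)) from exc
        trials.append((rec, judg))
    return ResultSet(code=header["code"], group_id=header["group_id"],
                     participant_id=header["participant_id"], trials=trials,
                     engine_seed=int(header["engine_seed"]),
                     schema_version=int(header["schema_version"]))


def read_results(stream: str | bytes | IO, format: str = "csv") -> ResultSet:
    """Inverse of :func:`write_results`; invariant violations become located errors."""
    if hasattr(stream, "read"):
        data = stream.read()
    else:
        data = stream
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    if format == "csv":
        return _read_csv(data)
    if format == "jsonl":
        return _read_jsonl(data)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")


def backup_and_payload(rs: ResultSet, op_log: Optional[list] = None) -> tuple[dict, dict]:
    """Build the local-backup document and the HTTP-post payload (no network).

    The backup document is constructed strictly before the payload — this is
    the crash-safety contract of the original tool, where a browser-local copy
    exists even if the upload fails.  ``op_log``, when given, records the
    operation order for auditing.  The payload is a single JSON-able object
    keyed by participant id and parses back to the full result set.
    """
    backup = {
        "kind": "local_backup",
        "code": rs.code,
        "group_id": rs.group_id,
        "participant_id": rs.participant_id,
        "engine_seed": rs.engine_seed,
        "schema_version": rs.schema_version,
        "trials": [_trial_to_obj(rec, judg) for rec, judg in rs.trials],
    }
    if op_log is not None:
        op_log.append(("backup", rs.participant_id))
    payload = {
        rs.participant_id: {
            "code": rs.code,
            "group_id": rs.group_id,
            "engine_seed": rs.engine_seed,
            "schema_version": rs.schema_version,
            "results": write_results(rs, "jsonl").decode("utf-8"),
        }
    }
    if op_log is not None:
        op_log.append(("payload", rs.participant_id))
    return backup, payload


def payload_to_results(payload: dict) -> ResultSet:
    """Recover the full result set from a post payload."""
    (participant_id, body), = payload.items()
    return read_results(body["results"], "jsonl")
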