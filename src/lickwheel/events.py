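"""Event-log data model, CSV serialization and validation.

A session is represented as a :class:`SessionLog`: a metadata record plus an
ordered sequence of timestamped :class:`Event` rows.  This is the single
interchange format between the task engine and the analysis layer.  On disk a
log is a plain UTF-8 CSV with ``#``-prefixed ``key=value`` metadata lines
followed by a ``time_ms,code,value`` header and one event per row.

Timestamps are integer milliseconds from session start.  The event ``value``
is an integer payload whose meaning depends on the code: spout index for
``lick``/``spout_extend_cmd``, rotation direction (+1/-1) for
``rotation_tick``, tone frequency in Hz for ``tone_on``, zone index for
``zone_enter``, solution index for ``solenoid_open``, laser frequency for
``laser_on``, trial index for ``trial_start``/``trial_end``; 0 when unused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

SCHEMA_VERSION = 1

REQUIRED_METADATA = ("session_id", "task_kind", "config_digest", "seed", "schema_version")


class EventCode(str, Enum):
    SESSION_START = "session_start"
    SESSION_END = "session_end"
    TRIAL_START = "trial_start"
    TRIAL_END = "trial_end"
    LICK = "lick"
    SOLENOID_OPEN = "solenoid_open"
    SPOUT_EXTEND_CMD = "spout_extend_cmd"
    SPOUT_RETRACT_CMD = "spout_retract_cmd"
    BRAKE_ON = "brake_on"
    BRAKE_OFF = "brake_off"
    TONE_ON = "tone_on"
    TONE_OFF = "tone_off"
    LASER_ON = "laser_on"
    LASER_OFF = "laser_off"
    ROTATION_TICK = "rotation_tick"
    ZONE_ENTER = "zone_enter"


_CODE_BY_NAME = {c.value: c for c in EventCode}

# on/off actuator families whose events must strictly alternate within a log
_ON_OFF_FAMILIES = {
    "brake": (EventCode.BRAKE_ON, EventCode.BRAKE_OFF),
    "tone": (EventCode.TONE_ON, EventCode.TONE_OFF),
    "laser": (EventCode.LASER_ON, EventCode.LASER_OFF),
}


@dataclass(frozen=True)
class Event:
    time_ms: int
    code: EventCode
    value: int = 0


@dataclass
class SessionLog:
    """Metadata + ordered event sequence for one behavioral session.

    ``metadata`` is a flat string->string mapping.  The keys in
    :data:`REQUIRED_METADATA` must be present; engines add task-specific keys
    (e.g. ``active_direction``, ``ticks_per_rotation``) that analysis
    functions read back.
    """

    metadata: dict[str, str]
    events: list[Event] = field(default_factory=list)

    @property
    def task_kind(self) -> str:
        return self.metadata["task_kind"]

    @property
    def duration_ms(self) -> int:
        return self.events[-1].time_ms if self.events else 0

    def times(self, code: EventCode) -> list[int]:
        return [e.time_ms for e in self.events if e.code is code]

    def of(self, code: EventCode) -> list[Event]:
        return [e for e in self.events if e.code is code]

    def meta_int(self, key: str, default: int | None = None) -> int:
        if key in self.metadata:
            return int(self.metadata[key])
        if default is None:
            raise KeyError(key)
        return default


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_log`."""

    event_index: int  # -1 for log-level violations
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] event {self.event_index}: {self.message}"


def validate_log(log: SessionLog) -> list[Violation]:
    """Check every structural invariant of a session log.

    Violations are returned as data, not raised: an empty list means the log
    is valid.  Each violation names the offending event index and the rule.
    """
    v: list[Violation] = []
    for key in REQUIRED_METADATA:
        if key not in log.metadata:
            v.append(Violation(-1, "metadata", f"missing required metadata key {key!r}"))

    ev = log.events
    if not ev:
        v.append(Violation(-1, "structure", "log has no events"))
        return v

    if ev[0].code is not EventCode.SESSION_START or ev[0].time_ms != 0:
        v.append(Violation(0, "structure", "first event must be session_start at time 0"))
    if ev[-1].code is not EventCode.SESSION_END:
        v.append(Violation(len(ev) - 1, "structure", "last event must be session_end"))
    n_start = sum(1 for e in ev if e.code is EventCode.SESSION_START)
    n_end = sum(1 for e in ev if e.code is EventCode.SESSION_END)
    if n_start != 1:
        v.append(Violation(-1, "structure", f"expected exactly one session_start, found {n_start}"))
    if n_end != 1:
        v.append(Violation(-1, "structure", f"expected exactly one session_end, found {n_end}"))

    last_t = 0
    for i, e in enumerate(ev):
        if e.time_ms < 0:
            v.append(Violation(i, "time", f"negative timestamp {e.time_ms}"))
        if e.time_ms < last_t:
            v.append(
                Violation(i, "monotonicity", f"timestamp {e.time_ms} before previous {last_t}")
            )
        last_t = max(last_t, e.time_ms)

    # trial pairing: trial_start / trial_end strictly alternate, consecutive
    # 0-based indices carried in the value payload
    expect_index = 0
    in_trial = False
    for i, e in enumerate(ev):
        if e.code is EventCode.TRIAL_START:
            if in_trial:
                v.append(Violation(i, "trial_pairing", "trial_start while previous trial open"))
            if e.value != expect_index:
                v.append(
                    Violation(
                        i, "trial_index", f"expected trial index {expect_index}, got {e.value}"
                    )
                )
            in_trial = True
        elif e.code is EventCode.TRIAL_END:
            if not in_trial:
                v.append(Violation(i, "trial_pairing", "trial_end without open trial"))
            else:
                expect_index += 1
            in_trial = False
    if in_trial:
        v.append(Violation(len(ev) - 1, "trial_pairing", "trial left open at session_end"))

    # on/off alternation per actuator family; a trailing *_on is terminated
    # by session_end and is legal
    for fam, (on, off) in _ON_OFF_FAMILIES.items():
        state = False
        for i, e in enumerate(ev):
            if e.code is on:
                if state:
                    v.append(Violation(i, f"{fam}_pairing", f"{on.value} while already on"))
                state = True
            elif e.code is off:
                if not state:
                    v.append(Violation(i, f"{fam}_pairing", f"{off.value} while already off"))
                state = False

    # the wheel cannot move while braked
    braked = False
    for i, e in enumerate(ev):
        if e.code is EventCode.BRAKE_ON:
            braked = True
        elif e.code is EventCode.BRAKE_OFF:
            braked = False
        elif e.code is EventCode.ROTATION_TICK and braked:
            v.append(Violation(i, "brake", "rotation_tick while brake engaged"))

    return v


def write_log(log: SessionLog, path: Union[str, Path]) -> None:
    """Write a validated log as a single-file CSV session.

    Refuses to write an invalid log; the raised error lists every violation.
    Round-trips bit-exactly through :func:`read_log`.
    """
    violations = validate_log(log)
    if violations:
        detail = "; ".join(str(x) for x in violations)
        raise ValueError(f"refusing to write invalid log: {detail}")
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in log.metadata.items()]
    lines.append("time_ms,code,value")
    lines.extend(f"{e.time_ms},{e.code.value},{e.value}" for e in log.events)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_log(path: Union[str, Path]) -> SessionLog:
    """Read and validate a session log written by :func:`write_log`.

    Malformed rows and unknown event codes raise ``ValueError`` naming the
    offending line number; a structurally invalid log raises as well.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    events: list[Event] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
                key, _, val = body.partition("=")
                metadata[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != "time_ms,code,value":
                    raise ValueError(f"{path}:{lineno}: expected header 'time_ms,code,value'")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            t_s, code_s, val_s = parts
            try:
                t = int(t_s)
                val = int(val_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field: {exc}") from None
            code = _CODE_BY_NAME.get(code_s)
            if code is None:
                raise ValueError(f"{path}:{lineno}: unknown event code {code_s!r}")
            events.append(Event(t, code, val))
    log = SessionLog(metadata=metadata, events=events)
    violations = validate_log(log)
    if violations:
        detail = "; ".join(str(x) for x in violations)
        raise ValueError(f"{path}: invalid log: {detail}")
    return log


def iter_trials(log: SessionLog) -> Iterable[tuple[int, int, int, list[Event]]]:
    """Yield ``(trial_index, start_ms, end_ms, events_within)`` per trial.

    Events strictly inside ``[start_ms, end_ms]`` (by log position, so
    same-millisecond boundary events stay with their trial) are included.
    """
    start_i = None
    for i, e in enumerate(log.events):
        if e.code is EventCode.TRIAL_START:
            start_i = i
        elif e.code is EventCode.TRIAL_END and start_i is not None:
            seg = log.events[start_i : i + 1]
            yield log.events[start_i].value, log.events[start_i].time_ms, e.time_ms, seg
            start_i = None
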