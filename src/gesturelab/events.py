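"""Domain model and I/O for annotated surgical-gesture event logs.

A procedure (one participant performing one simulator part-procedure once)
is annotated as a sequence of gesture bouts, each with a start and stop time
in seconds.  Logs are exchanged as delimited text in the dialect of a BORIS
aggregated-events export: one row per bout with an observation id, a subject
field, a behavior label and start/stop seconds.  The dialect (column names,
label aliases, how metadata is encoded in the observation id) is configurable
because exports vary between annotation set-ups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Gesture(str, Enum):
    """The five general surgical gestures used for annotation."""

    REGULAR_DISSECTION = "regular_dissection"
    HEMOSTATIC_CONTROL = "hemostatic_control"
    CLIP_APPLICATION = "clip_application"
    NEEDLE_HANDLING = "needle_handling"
    SUTURING = "suturing"


class Group(str, Enum):
    NOVICE = "novice"
    EXPERIENCED = "experienced"


class Module(str, Enum):
    """The three part-procedures of the simulated prostatectomy."""

    BLADDER_NECK = "bladder_neck"
    NEUROVASCULAR_BUNDLE = "neurovascular_bundle"
    ANASTOMOSIS = "anastomosis"


#: Single-letter codes used in observation ids ("P01-B-2" = bladder neck, rep 2).
MODULE_CODES: dict[str, Module] = {
    "B": Module.BLADDER_NECK,
    "N": Module.NEUROVASCULAR_BUNDLE,
    "U": Module.ANASTOMOSIS,
}
CODE_OF_MODULE: dict[Module, str] = {m: c for c, m in MODULE_CODES.items()}

#: Default mapping from annotation labels (as typed by an annotator) onto the
#: five-gesture model.  Keys are matched case-insensitively after stripping.
DEFAULT_ALIASES: dict[str, Gesture] = {
    "regular dissection": Gesture.REGULAR_DISSECTION,
    "regular_dissection": Gesture.REGULAR_DISSECTION,
    "dissection": Gesture.REGULAR_DISSECTION,
    "sharp dissection": Gesture.REGULAR_DISSECTION,
    "blunt dissection": Gesture.REGULAR_DISSECTION,
    "hemostatic control": Gesture.HEMOSTATIC_CONTROL,
    "hemostatic_control": Gesture.HEMOSTATIC_CONTROL,
    "hemostasis": Gesture.HEMOSTATIC_CONTROL,
    "application of clips": Gesture.CLIP_APPLICATION,
    "clip application": Gesture.CLIP_APPLICATION,
    "clip_application": Gesture.CLIP_APPLICATION,
    "clips": Gesture.CLIP_APPLICATION,
    "clip": Gesture.CLIP_APPLICATION,
    "needle handling": Gesture.NEEDLE_HANDLING,
    "needle_handling": Gesture.NEEDLE_HANDLING,
    "suturing": Gesture.SUTURING,
    "suture": Gesture.SUTURING,
}


class EventLogError(ValueError):
    """Raised for malformed event-log content or invalid domain objects."""


@dataclass(frozen=True)
class GestureEvent:
    """One annotated bout of one gesture.

    Parameters
    ----------
    gesture : Gesture
        One of the five gesture labels.
    start_s, stop_s : float
        Bout boundaries in seconds; ``stop_s`` must exceed ``start_s``
        (zero-length bouts are rejected).
    arm : int, optional
        Robotic arm (1-3) the bout was annotated on, when recorded.
    """

    gesture: Gesture
    start_s: float
    stop_s: float
    arm: int | None = None

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise EventLogError(f"start_s must be >= 0, got {self.start_s}")
        if not self.stop_s > self.start_s:
            raise EventLogError(
                f"stop_s must exceed start_s (got start={self.start_s}, "
                f"stop={self.stop_s}); zero-length bouts are rejected"
            )
        if self.arm is not None and self.arm not in (1, 2, 3):
            raise EventLogError(f"arm must be 1, 2 or 3, got {self.arm}")

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass(frozen=True)
class ProcedureLog:
    """All gesture events of one participant x module x repetition.

    Events are stored sorted by start time (ties broken by stop time) and may
    overlap each other: different robotic arms can be active simultaneously.
    An empty procedure is invalid — feature extraction has nothing to measure.
    """

    participant_id: str
    group: Group
    module: Module
    repetition: int
    events: tuple[GestureEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise EventLogError(
                f"procedure {self.participant_id}/{self.module.value}/"
                f"rep{self.repetition} has no events"
            )
        if not 1 <= int(self.repetition) <= 3:
            raise EventLogError(f"repetition must be 1..3, got {self.repetition}")
        ordered = tuple(
            sorted(self.events, key=lambda e: (e.start_s, e.stop_s))
        )
        object.__setattr__(self, "events", ordered)

    @property
    def observation_id(self) -> str:
        return f"{self.participant_id}-{CODE_OF_MODULE[self.module]}-{self.repetition}"


@dataclass(frozen=True)
class CohortDesign:
    """Who performed what: enrolment and completion structure of a cohort.

    ``completion_mask`` maps participant id -> set of (module, repetition)
    cells that exist.  A participant is a *completer* iff every
    module x repetition cell exists; only completers enter repeated-measures
    and standard-setting analyses.
    """

    groups: Mapping[str, Group]
    modules: tuple[Module, ...] = tuple(Module)
    repetitions: int = 3
    completion_mask: Mapping[str, frozenset[tuple[Module, int]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        full = self.full_cell_set()
        mask = {
            pid: frozenset(self.completion_mask.get(pid, full))
            for pid in self.groups
        }
        object.__setattr__(self, "completion_mask", mask)
        for pid, cells in mask.items():
            extra = cells - full
            if extra:
                raise EventLogError(f"participant {pid} has cells outside the design: {extra}")

    def full_cell_set(self) -> frozenset[tuple[Module, int]]:
        return frozenset(
            (m, r) for m in self.modules for r in range(1, self.repetitions + 1)
        )

    def is_completer(self, participant_id: str) -> bool:
        return self.completion_mask[participant_id] == self.full_cell_set()

    @property
    def completers(self) -> list[str]:
        return [p for p in self.groups if self.is_completer(p)]

    @property
    def n_novices(self) -> int:
        return sum(g is Group.NOVICE for g in self.groups.values())

    @property
    def n_experienced(self) -> int:
        return sum(g is Group.EXPERIENCED for g in self.groups.values())


@dataclass(frozen=True)
class Dialect:
    """Column mapping and label aliases for the event-log text format.

    Times are decimal seconds.  The observation id encodes participant,
    module and repetition as ``PID-MODULECODE-REP`` (e.g. ``N01-B-2``); the
    subject column carries the skill-group label.  Comma- or tab-separation
    is autodetected from the header when reading.
    """

    observation_col: str = "Observation id"
    subject_col: str = "Subject"
    behavior_col: str = "Behavior"
    start_col: str = "Start (s)"
    stop_col: str = "Stop (s)"
    arm_col: str = "Modifiers"  # optional in files
    aliases: Mapping[str, Gesture] = field(default_factory=lambda: dict(DEFAULT_ALIASES))
    group_labels: Mapping[str, Group] = field(
        default_factory=lambda: {
            "novice": Group.NOVICE,
            "experienced": Group.EXPERIENCED,
            "experienced surgeon": Group.EXPERIENCED,
        }
    )
    module_codes: Mapping[str, Module] = field(default_factory=lambda: dict(MODULE_CODES))

    def with_aliases(self, extra: Mapping[str, Gesture]) -> "Dialect":
        merged = {**self.aliases, **extra}
        return replace(self, aliases=merged)

    def resolve_gesture(self, label: str) -> Gesture:
        key = label.strip().lower()
        try:
            return self.aliases[key]
        except KeyError:
            raise EventLogError(
                f"unknown behavior label {label!r}; add it to the alias table"
            ) from None

    def resolve_group(self, label: str) -> Group:
        key = label.strip().lower()
        try:
            return self.group_labels[key]
        except KeyError:
            raise EventLogError(f"unknown group/subject label {label!r}") from None

    def parse_observation_id(self, obs_id: str) -> tuple[str, Module, int]:
        parts = obs_id.strip().rsplit("-", 2)
        if len(parts) != 3:
            raise EventLogError(
                f"observation id {obs_id!r} does not match 'PID-MODULE-REP'"
            )
        pid, code, rep = parts
        if code not in self.module_codes:
            raise EventLogError(
                f"observation id {obs_id!r}: unknown module code {code!r}"
            )
        try:
            repetition = int(rep)
        except ValueError:
            raise EventLogError(
                f"observation id {obs_id!r}: repetition {rep!r} is not an integer"
            ) from None
        return pid, self.module_codes[code], repetition


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_event_log(path: str | Path, dialect: Dialect | None = None) -> list[ProcedureLog]:
    """Read a delimited event-log file into :class:`ProcedureLog` records.

    Rows are grouped by observation id; every row lands in exactly one log.
    Behavior labels are mapped through the dialect's alias table; group,
    module and repetition are parsed from the subject and observation-id
    fields.  A header-only file yields an empty list.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise EventLogError(f"{path}: empty file (no header row)")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        required = [
            dialect.observation_col,
            dialect.subject_col,
            dialect.behavior_col,
            dialect.start_col,
            dialect.stop_col,
        ]
        for col in required:
            if col not in header:
                raise EventLogError(f"{path}: missing required column {col!r}")
        has_arm = dialect.arm_col in header

        grouped: dict[str, list[GestureEvent]] = {}
        meta: dict[str, tuple[str, Group, Module, int]] = {}
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            obs = row[dialect.observation_col]
            gesture = dialect.resolve_gesture(row[dialect.behavior_col])
            try:
                start = float(row[dialect.start_col])
                stop = float(row[dialect.stop_col])
            except (TypeError, ValueError):
                raise EventLogError(f"{path}: row {i}: non-numeric start/stop") from None
            if not stop > start:
                raise EventLogError(
                    f"{path}: row {i}: stop ({stop}) must exceed start ({start})"
                )
            arm = None
            if has_arm and row.get(dialect.arm_col, "").strip():
                try:
                    arm = int(row[dialect.arm_col])
                except ValueError:
                    raise EventLogError(
                        f"{path}: row {i}: arm {row[dialect.arm_col]!r} is not 1-3"
                    ) from None
            if obs not in meta:
                pid, module, rep = dialect.parse_observation_id(obs)
                group = dialect.resolve_group(row[dialect.subject_col])
                meta[obs] = (pid, group, module, rep)
            grouped.setdefault(obs, []).append(
                GestureEvent(gesture=gesture, start_s=start, stop_s=stop, arm=arm)
            )

    logs = []
    for obs, events in grouped.items():
        pid, group, module, rep = meta[obs]
        logs.append(
            ProcedureLog(
                participant_id=pid,
                group=group,
                module=module,
                repetition=rep,
                events=tuple(events),
            )
        )
    return logs


def write_event_log(
    logs: Iterable[ProcedureLog],
    path: str | Path,
    dialect: Dialect | None = None,
    delimiter: str = ",",
) -> None:
    """Write procedure logs as a delimited text file re-readable by
    :func:`read_event_log` (read of write is the identity on event content)."""
    dialect = dialect or Dialect()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(
            [
                dialect.observation_col,
                dialect.subject_col,
                dialect.behavior_col,
                dialect.start_col,
                dialect.stop_col,
                dialect.arm_col,
            ]
        )
        for log in logs:
            for ev in log.events:
                writer.writerow(
                    [
                        log.observation_id,
                        log.group.value,
                        ev.gesture.value,
                        repr(ev.start_s),  # shortest repr: exact float round-trip
                        repr(ev.stop_s),
                        "" if ev.arm is None else ev.arm,
                    ]
                )


def sort_logs(logs: Sequence[ProcedureLog]) -> list[ProcedureLog]:
    """Deterministic ordering: by participant, module (design order), repetition."""
    module_order = {m: i for i, m in enumerate(Module)}
    return sorted(
        logs, key=lambda l: (l.participant_id, module_order[l.module], l.repetition)
    )
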