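"""Annotated call-event tables: data model, readers and writers.

The pipeline consumes one row per vocalization (session, experimental
phase, caller, onset/offset seconds, vocal type).  Two dialects are
supported: a plain CSV with canonical column names, and Raven-style
selection tables (tab-separated, ``Begin Time (s)`` / ``End Time (s)``
columns) as produced by manual annotation software.  Times are stored
in seconds relative to the start of the phase, written at 1 ms
precision — ample for calls that last ~25 ms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_PHASE_DURATION = 900.0  # seconds; each experimental phase is 15 min


class Phase(str, enum.Enum):
    """Experimental phase: solo before, face-to-face, solo after."""

    PRE = "PRE"
    F2F = "F2F"
    POST = "POST"


class VocalType(str, enum.Enum):
    CALL = "call"
    SONG = "song"
    TRILL = "trill"


class FormatError(ValueError):
    """Input table does not have the expected shape (e.g. missing column)."""


class ValidationError(ValueError):
    """A row violates an event invariant (e.g. offset before onset)."""


@dataclass(frozen=True, order=True)
class CallEvent:
    """One vocalization.

    Ordering is (onset, caller_id) so that sorting a list of events gives
    the canonical within-phase order, with lexicographic caller id
    breaking exact onset ties.
    """

    onset: float
    caller_id: str = field(compare=True)
    offset: float = field(compare=False)
    session_id: str = field(compare=False, default="")
    phase: Phase = field(compare=False, default=Phase.F2F)
    vocal_type: VocalType = field(compare=False, default=VocalType.CALL)

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValidationError(
                f"offset ({self.offset}) must exceed onset ({self.onset}) "
                f"for caller {self.caller_id!r} in session {self.session_id!r}"
            )
        if self.onset < 0:
            raise ValidationError(f"negative onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SessionRecord:
    """One experimental session: a subject/facing pair and its events.

    ``pair`` is ordered (subject first — the bird present in all three
    phases — then the facing bird, present only face-to-face).
    """

    session_id: str
    pair: tuple[str, str]
    events: list[CallEvent]

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        subject, facing = self.pair
        for ev in self.events:
            if ev.phase is not Phase.F2F and ev.caller_id != subject:
                raise ValidationError(
                    f"session {self.session_id!r}: caller {ev.caller_id!r} in "
                    f"{ev.phase.value} phase, but only subject {subject!r} is present"
                )
            if ev.caller_id not in (subject, facing):
                raise ValidationError(
                    f"session {self.session_id!r}: unknown caller {ev.caller_id!r}"
                )

    @property
    def subject(self) -> str:
        return self.pair[0]

    @property
    def facing(self) -> str:
        return self.pair[1]

    def events_in(self, phase: Phase) -> list[CallEvent]:
        return [ev for ev in self.events if ev.phase is phase]


@dataclass
class ExperimentConfig:
    """Analysis-wide knobs, with the conventional defaults."""

    phase_duration: float = DEFAULT_PHASE_DURATION
    interval_threshold_for_summary: float = 10.0
    log_base: float = 10.0
    n_permutations: int = 10_000
    percentile_level: float = 95.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_duration <= 0 or self.interval_threshold_for_summary <= 0:
            raise ValueError("durations and thresholds must be positive")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be positive")
        if not 0 < self.percentile_level < 100:
            raise ValueError("percentile_level must lie in (0, 100)")


CSV_COLUMNS = ["session_id", "phase", "caller_id", "onset_s", "offset_s", "vocal_type"]


def _event_from_row(row: Mapping, index: int) -> CallEvent:
    try:
        phase = Phase(str(row["phase"]).upper())
    except ValueError:
        raise ValidationError(
            f"row {index}: unknown phase label {row['phase']!r}"
        ) from None
    try:
        vtype = VocalType(str(row["vocal_type"]).lower())
    except ValueError:
        raise ValidationError(
            f"row {index}: unknown vocal type {row['vocal_type']!r}"
        ) from None
    try:
        return CallEvent(
            session_id=str(row["session_id"]),
            phase=phase,
            caller_id=str(row["caller_id"]),
            onset=float(row["onset_s"]),
            offset=float(row["offset_s"]),
            vocal_type=vtype,
        )
    except ValidationError as err:
        raise ValidationError(f"row {index}: {err}") from None


def read_call_table(
    path: str | Path,
    dialect: str = "csv",
    *,
    column_map: Mapping[str, str] | None = None,
    channel_map: Mapping[str, str] | None = None,
    session_id: str | None = None,
    phase: Phase | str | None = None,
    vocal_type: VocalType | str = VocalType.CALL,
) -> list[CallEvent]:
    """Read an annotation table into validated, sorted call events.

    Parameters
    ----------
    path : path to the table file.
    dialect : ``"csv"`` (canonical columns) or ``"raven"`` (tab-separated
        selection table with ``Begin Time (s)`` / ``End Time (s)``).
    column_map : for the raven dialect, maps canonical column names
        (``caller``, ``vocal_type``) to columns in the file.  By default
        the ``Channel`` column carries the caller.
    channel_map : raven only — translate channel values to caller ids
        (caller identification from audio happens upstream; the mapping
        is supplied by the user).
    session_id, phase, vocal_type : raven only — metadata not stored in
        selection tables.

    Events are returned sorted by (onset, caller_id) within the file.
    """
    path = Path(path)
    if dialect == "csv":
        frame = pd.read_csv(path, dtype={"session_id": str, "caller_id": str})
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        events = [
            _event_from_row(row, i + 2)  # +2: header line plus 1-based numbering
            for i, row in enumerate(frame.to_dict("records"))
        ]
    elif dialect == "raven":
        frame = pd.read_csv(path, sep="\t")
        colmap = {"caller": "Channel", "vocal_type": None}
        if column_map:
            colmap.update(column_map)
        for col in ("Begin Time (s)", "End Time (s)", colmap["caller"]):
            if col not in frame.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        if phase is None:
            raise FormatError("raven dialect requires an explicit phase")
        phase = Phase(phase) if not isinstance(phase, Phase) else phase
        default_vtype = VocalType(vocal_type)
        events = []
        for i, row in enumerate(frame.to_dict("records")):
            caller = str(row[colmap["caller"]])
            if channel_map is not None:
                caller = channel_map.get(caller, caller)
            vtype = default_vtype
            if colmap["vocal_type"] and colmap["vocal_type"] in frame.columns:
                vtype = VocalType(str(row[colmap["vocal_type"]]).lower())
            try:
                events.append(
                    CallEvent(
                        session_id=session_id or path.stem,
                        phase=phase,
                        caller_id=caller,
                        onset=float(row["Begin Time (s)"]),
                        offset=float(row["End Time (s)"]),
                        vocal_type=vtype,
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"row {i + 2}: {err}") from None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return sorted(events)


def write_call_table(events: Iterable[CallEvent], path: str | Path) -> None:
    """Write events in the canonical CSV dialect (times at 1 ms precision)."""
    frame = events_to_frame(events)
    frame.to_csv(path, index=False, float_format="%.3f")


def events_to_frame(events: Iterable[CallEvent]) -> pd.DataFrame:
    rows = [
        {
            "session_id": ev.session_id,
            "phase": ev.phase.value,
            "caller_id": ev.caller_id,
            "onset_s": ev.onset,
            "offset_s": ev.offset,
            "vocal_type": ev.vocal_type.value,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def filter_events(
    events: Sequence[CallEvent],
    vocal_type: VocalType | str | None = None,
    phase: Phase | str | None = None,
) -> list[CallEvent]:
    """Keep events matching both selectors (None matches everything)."""
    if vocal_type is not None:
        vocal_type = VocalType(vocal_type)
    if phase is not None:
        phase = Phase(phase)
    return [
        ev
        for ev in events
        if (vocal_type is None or ev.vocal_type is vocal_type)
        and (phase is None or ev.phase is phase)
    ]


def group_sessions(
    events: Sequence[CallEvent],
    pairs: Mapping[str, tuple[str, str]] | None = None,
) -> list[SessionRecord]:
    """Assemble SessionRecords from a flat event list.

    If ``pairs`` (session_id -> ordered (subject, facing)) is omitted,
    the subject is inferred as the caller of the solo phases and the
    facing bird as the other face-to-face caller.
    """
    by_session: dict[str, list[CallEvent]] = {}
    for ev in events:
        by_session.setdefault(ev.session_id, []).append(ev)
    records = []
    for sid, evs in sorted(by_session.items()):
        if pairs is not None:
            pair = pairs[sid]
        else:
            solo = {e.caller_id for e in evs if e.phase is not Phase.F2F}
            everyone = {e.caller_id for e in evs}
            if len(solo) != 1:
                raise ValidationError(
                    f"session {sid!r}: cannot infer subject from solo phases "
                    f"(callers seen: {sorted(solo)})"
                )
            subject = solo.pop()
            others = everyone - {subject}
            if len(others) > 1:
                raise ValidationError(f"session {sid!r}: more than two callers")
            facing = others.pop() if others else ""
            pair = (subject, facing)
        records.append(SessionRecord(session_id=sid, pair=pair, events=evs))
    return records
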