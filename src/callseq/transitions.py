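"""Call transitions: consecutive-call pairs within a session phase.

A transition is *exchange* when the two calls come from different birds
and *repeated* when the same bird calls twice in a row.  Its interval is
offset-to-onset (end of the preceding call to start of the following
one), so overlapping exchange calls give a negative interval.  Negative
intervals are kept here; they are excluded only when intervals are
log-transformed downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events_io import CallEvent


class TransitionKind(str, enum.Enum):
    EXCHANGE = "exchange"
    REPEATED = "repeated"


@dataclass(frozen=True)
class Transition:
    preceding: CallEvent
    following: CallEvent

    @property
    def kind(self) -> TransitionKind:
        if self.preceding.caller_id == self.following.caller_id:
            return TransitionKind.REPEATED
        return TransitionKind.EXCHANGE

    @property
    def interval(self) -> float:
        """Offset-to-onset gap in seconds; negative when calls overlap."""
        return self.following.onset - self.preceding.offset

    @property
    def overlap(self) -> bool:
        return self.interval < 0


def build_transitions(events: Sequence[CallEvent]) -> list[Transition]:
    """Pair consecutive events of one session phase into transitions.

    Input must already be sorted by onset and come from a single session
    and phase: transitions never span a session or phase boundary.
    N events yield max(0, N-1) transitions.
    """
    if len({(ev.session_id, ev.phase) for ev in events}) > 1:
        raise ValueError("events span more than one session/phase")
    onsets = [ev.onset for ev in events]
    if onsets != sorted(onsets):
        raise ValueError("events must be sorted by onset")
    return [Transition(a, b) for a, b in zip(events, events[1:])]


def split_by_kind(
    transitions: Iterable[Transition],
) -> tuple[list[Transition], list[Transition]]:
    """Partition into (exchange, repeated)."""
    exchange = [t for t in transitions if t.kind is TransitionKind.EXCHANGE]
    repeated = [t for t in transitions if t.kind is TransitionKind.REPEATED]
    return exchange, repeated


def count_overlaps(transitions: Iterable[Transition]) -> int:
    return sum(t.overlap for t in transitions)


def intervals(transitions: Iterable[Transition]) -> np.ndarray:
    return np.array([t.interval for t in transitions], dtype=float)


def fraction_within(values: Sequence[float], threshold: float) -> float:
    """Proportion of intervals at or below ``threshold`` seconds.

    Negative (overlap) intervals count as within.  Undefined for an
    empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("fraction_within is undefined for an empty interval list")
    return float(np.mean(arr <= threshold))


def pooled_transitions(
    session_phase_events: Iterable[Sequence[CallEvent]],
) -> list[Transition]:
    """Build transitions per (session, phase) block and concatenate.

    Pooling across sessions without session covariates mirrors how the
    face-to-face sessions are analysed jointly.
    """
    out: list[Transition] = []
    for events in session_phase_events:
        out.extend(build_transitions(events))
    return out


def transitions_to_frame(transitions: Iterable[Transition]) -> pd.DataFrame:
    rows = [
        {
            "session_id": t.preceding.session_id,
            "kind": t.kind.value,
            "preceding_caller": t.preceding.caller_id,
            "following_caller": t.following.caller_id,
            "interval_s": t.interval,
            "overlap": t.overlap,
        }
        for t in transitions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "kind",
            "preceding_caller",
            "following_caller",
            "interval_s",
            "overlap",
        ],
    )
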