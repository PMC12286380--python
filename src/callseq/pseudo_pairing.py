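"""Pseudo-turn-taking null: re-pair call tracks across sessions.

The short mode of exchange intervals could in principle arise by chance
from two birds calling independently.  The null dataset built here
re-pairs each subject's face-to-face call track with the facing bird's
track taken from a *different* session of the same ordered pair, so the
two tracks are statistically independent while every marginal property
(call times, counts, pair identity, subject/facing roles) is preserved.
Sessions are re-paired by a seeded derangement of each pair's session
indices, so no pseudo session reproduces a real one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events_io import CallEvent, Phase, SessionRecord
from .transitions import Transition, build_transitions, count_overlaps, intervals, split_by_kind


@dataclass
class PseudoSession:
    """A subject track and an independently recorded facing track, merged."""

    source_subject_session: str
    source_facing_session: str
    pair: tuple[str, str]
    events: list[CallEvent]

    def __post_init__(self) -> None:
        if self.source_subject_session == self.source_facing_session:
            raise ValueError("pseudo session must combine two distinct sessions")
        self.events = sorted(self.events)


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("a derangement needs at least 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def make_pseudo_sessions(
    sessions: list[SessionRecord], seed: int = 0
) -> list[PseudoSession]:
    """One pseudo session per real session, facing tracks deranged within pair.

    Re-pairing is restricted to sessions of the same ordered (subject,
    facing) pair; a pair recorded only once cannot be deranged and is an
    error.
    """
    rng = np.random.default_rng(seed)
    by_pair: dict[tuple[str, str], list[SessionRecord]] = {}
    for rec in sessions:
        by_pair.setdefault(rec.pair, []).append(rec)
    out: list[PseudoSession] = []
    for pair in sorted(by_pair):
        group = sorted(by_pair[pair], key=lambda r: r.session_id)
        if len(group) < 2:
            raise ValueError(
                f"pair {pair} has a single session; cannot build pseudo pairing"
            )
        perm = random_derangement(len(group), rng)
        for i, rec in enumerate(group):
            donor = group[perm[i]]
            subject_track = [
                ev for ev in rec.events_in(Phase.F2F) if ev.caller_id == rec.subject
            ]
            facing_track = [
                ev for ev in donor.events_in(Phase.F2F) if ev.caller_id == donor.facing
            ]
            out.append(
                PseudoSession(
                    source_subject_session=rec.session_id,
                    source_facing_session=donor.session_id,
                    pair=pair,
                    events=subject_track + facing_track,
                )
            )
    return out


def pseudo_transition_analysis(
    pseudo_sessions: list[PseudoSession],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled (exchange intervals, repeated intervals, overlap count)."""
    transitions: list[Transition] = []
    for ps in pseudo_sessions:
        # the merged track belongs to differing source sessions; retag so
        # build_transitions sees one homogeneous block
        retagged = sorted(
            CallEvent(
                session_id=f"pseudo:{ps.source_subject_session}+{ps.source_facing_session}",
                phase=Phase.F2F,
                caller_id=ev.caller_id,
                onset=ev.onset,
                offset=ev.offset,
                vocal_type=ev.vocal_type,
            )
            for ev in ps.events
        )
        transitions.extend(build_transitions(retagged))
    exchange, repeated = split_by_kind(transitions)
    return intervals(exchange), intervals(repeated), count_overlaps(transitions)
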