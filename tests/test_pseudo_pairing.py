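import itertools
from collections import Counter

import numpy as np
import pytest

from callseq.events_io import Phase, SessionRecord, VocalType, filter_events
from callseq.interval_mixture import fit_intervals
from callseq.pseudo_pairing import (
    make_pseudo_sessions,
    pseudo_transition_analysis,
    random_derangement,
)
from callseq.simulate import SimulationParams, simulate_experiment
from callseq.transitions import TransitionKind, build_transitions, intervals, pooled_transitions, split_by_kind
from conftest import has_concentrated_short_mode, make_event


def tiny_session(sid, subject, facing, subject_onsets, facing_onsets):
    events = [make_event(t, subject, session=sid) for t in subject_onsets]
    events += [make_event(t, facing, session=sid) for t in facing_onsets]
    return SessionRecord(session_id=sid, pair=(subject, facing), events=events)


class TestDerangement:
    def test_two_elements_forced_swap(self):
        assert random_derangement(2, np.random.default_rng(0)).tolist() == [1, 0]

    def test_matches_brute_force_enumeration(self):
        """Every sampled permutation of 4 lies in the enumerated derangement set."""
        valid = {
            p
            for p in itertools.permutations(range(4))
            if all(p[i] != i for i in range(4))
        }
        assert len(valid) == 9  # the subfactorial of 4
        rng = np.random.default_rng(1)
        seen = {tuple(random_derangement(4, rng)) for _ in range(200)}
        assert seen <= valid
        assert len(seen) == 9  # all derangements reachable

    def test_single_element_impossible(self):
        with pytest.raises(ValueError):
            random_derangement(1, np.random.default_rng(0))


class TestMakePseudoSessions:
    def test_two_sessions_swap_facing_tracks(self):
        s1 = tiny_session("S1", "A", "B", [1.0], [2.0])
        s2 = tiny_session("S2", "A", "B", [3.0], [4.0])
        pseudo = make_pseudo_sessions([s1, s2], seed=0)
        sources = {
            (p.source_subject_session, p.source_facing_session) for p in pseudo
        }
        assert sources == {("S1", "S2"), ("S2", "S1")}
        by_subject_source = {p.source_subject_session: p for p in pseudo}
        onsets = [e.onset for e in by_subject_source["S1"].events]
        assert onsets == [1.0, 4.0]  # A's own track + B's track from S2

    def test_single_session_pair_is_error(self):
        s1 = tiny_session("S1", "A", "B", [1.0], [2.0])
        with pytest.raises(ValueError, match="pair"):
            make_pseudo_sessions([s1], seed=0)

    def test_no_pseudo_session_reuses_its_own_pairing(self, contagion_sessions):
        pseudo = make_pseudo_sessions(contagion_sessions, seed=4)
        assert len(pseudo) == len(contagion_sessions)
        assert all(
            p.source_subject_session != p.source_facing_session for p in pseudo
        )

    def test_marginal_call_times_conserved(self, contagion_sessions):
        """Re-pairing only rearranges tracks; every call time survives."""
        pseudo = make_pseudo_sessions(contagion_sessions, seed=4)
        orig = Counter(
            (ev.caller_id, round(ev.onset, 6))
            for rec in contagion_sessions
            for ev in rec.events_in(Phase.F2F)
        )
        shuffled = Counter(
            (ev.caller_id, round(ev.onset, 6))
            for p in pseudo
            for ev in p.events
        )
        assert orig == shuffled

    def test_empty_facing_track_gives_only_repeated_transitions(self):
        s1 = tiny_session("S1", "A", "B", [1.0, 2.0, 3.0], [])
        s2 = tiny_session("S2", "A", "B", [4.0, 5.0], [])
        pseudo = make_pseudo_sessions([s1, s2], seed=0)
        ex, rep, _ = pseudo_transition_analysis(pseudo)
        assert len(ex) == 0 and len(rep) == 3


class TestNullBehaviour:
    def test_short_mode_destroyed_by_repairing(self, contagion_sessions):
        """Contagious responses create the short exchange mode; independence removes it."""
        blocks = [
            filter_events(rec.events_in(Phase.F2F), vocal_type=VocalType.CALL)
            for rec in contagion_sessions
        ]
        exchange, _ = split_by_kind(pooled_transitions(blocks))
        fit_orig = fit_intervals(intervals(exchange), seed=0)

        pseudo = make_pseudo_sessions(contagion_sessions, seed=4)
        ps_exchange, _, _ = pseudo_transition_analysis(pseudo)
        fit_pseudo = fit_intervals(ps_exchange, seed=0)
        assert fit_pseudo.weight_short < 0.5 * fit_orig.weight_short

    def test_independent_tracks_show_no_short_mode(self, independent_sessions):
        pseudo = make_pseudo_sessions(independent_sessions, seed=9)
        ps_exchange, _, _ = pseudo_transition_analysis(pseudo)
        fit = fit_intervals(ps_exchange, seed=0)
        assert not has_concentrated_short_mode(fit)

    def test_original_pairing_has_more_short_interval_mass(self):
        """Over several seeds, real pairing concentrates exchange intervals below 0.5 s."""
        for seed in range(5):
            params = SimulationParams(seed=seed, response_prob=0.7)
            sessions = simulate_experiment(
                params, n_subjects=2, sessions_per_pair=4, seed=seed
            )
            blocks = [
                filter_events(rec.events_in(Phase.F2F), vocal_type=VocalType.CALL)
                for rec in sessions
            ]
            exchange, _ = split_by_kind(pooled_transitions(blocks))
            orig = intervals(exchange)
            ps_exchange, _, _ = pseudo_transition_analysis(
                make_pseudo_sessions(sessions, seed=seed)
            )
            assert np.mean(orig < 0.5) > np.mean(ps_exchange < 0.5)

    def test_pseudo_interval_density_decays_monotonically(self, independent_sessions):
        """Without coupling, binned exchange-interval counts only decrease
        (up to counting noise) over (0, 10] s."""
        pseudo = make_pseudo_sessions(independent_sessions, seed=2)
        ps_exchange, _, _ = pseudo_transition_analysis(pseudo)
        # the far tail is Poisson-sparse; the trend is assessed where
        # bins carry meaningful counts
        hist, _ = np.histogram(ps_exchange, bins=np.arange(0.0, 5.5, 0.5))
        for prev, nxt in zip(hist, hist[1:]):
            assert nxt <= prev + 3.0 * np.sqrt(prev + 1.0)
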