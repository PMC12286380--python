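"""Seeded simulator of reactive two-bird calling sessions.

The generator produces the statistical structure the analysis assumes,
so every pipeline stage can be exercised without recordings.  Each bird
calls spontaneously as a renewal process with log10-normal gaps (the
*long*, independent-calling component); on hearing the partner's call
offset it may, with some probability, schedule a contagious response
after a log10-normal latency (the *short* component).  Latencies being
log10-normal makes mixture-parameter recovery a sharp test of the
analysis rather than an approximation.

Responses trigger on the partner's call *offset*: measured intervals
are offset-to-onset, so a response latency maps directly onto the
exchange interval it produces.  A response arriving inside the bird's
own refractory window is suppressed; a pending spontaneous call is
rescheduled (not cancelled) after a response fires, keeping marginal
rates interpretable.  A spontaneous call never starts while the partner
is audibly mid-call (it is deferred to the partner's offset), so
between-bird overlap can only come from a response latency shorter than
a call — with the default latency distribution, essentially never.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .events_io import CallEvent, Phase, SessionRecord, VocalType

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings.

    Defaults emulate the study conditions: 900 s phases, ~25 ms calls,
    response latencies centred near 0.19 s (10^-0.73), spontaneous gaps
    centred near 2.8 s (10^0.45) with wide spread.

    ``baseline_rate`` (calls/s) rescales the spontaneous gap
    distribution so its mean gap equals ``1/baseline_rate``; ``None``
    keeps the natural rate of the log10-normal gaps, ``0`` disables
    spontaneous calling entirely.
    """

    phase_duration: float = 900.0
    baseline_rate: float | None = None
    response_prob: float = 0.5
    response_latency_log10_mean: float = -0.73
    response_latency_log10_sd: float = 0.15
    self_interval_log10_mean: float = 0.45
    self_interval_log10_sd: float = 0.6
    call_duration: float = 0.0247
    refractory: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_duration <= 0 or self.call_duration <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.response_prob <= 1.0:
            raise ValueError("response_prob must lie in [0, 1]")
        if self.baseline_rate is not None and self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.response_latency_log10_sd <= 0 or self.self_interval_log10_sd <= 0:
            raise ValueError("latency/gap spreads must be positive")
        if self.refractory < self.call_duration:
            raise ValueError("refractory must be at least one call duration")

    @property
    def natural_mean_gap(self) -> float:
        """Mean of the unscaled log10-normal spontaneous gap, seconds."""
        s = self.self_interval_log10_sd * _LN10
        return 10.0**self.self_interval_log10_mean * math.exp(0.5 * s * s)

    @property
    def gap_scale(self) -> float:
        """Multiplier applied to raw gaps to realise ``baseline_rate``."""
        if self.baseline_rate is None:
            return 1.0
        if self.baseline_rate == 0.0:
            return math.inf
        return (1.0 / self.baseline_rate) / self.natural_mean_gap


def _simulate_tracks(
    params: SimulationParams,
    birds: list[str],
    rng: np.random.Generator,
    session_id: str,
    phase: Phase,
    rate_multipliers: dict[str, float] | None = None,
) -> list[CallEvent]:
    """Event-driven core shared by solo and face-to-face phases."""
    mult = rate_multipliers or {}
    scale = params.gap_scale
    dur = params.call_duration

    def gap(bird: str) -> float:
        if not math.isfinite(scale):
            return math.inf
        g = 10.0 ** rng.normal(
            params.self_interval_log10_mean, params.self_interval_log10_sd
        )
        return g * scale / mult.get(bird, 1.0)

    def latency() -> float:
        return 10.0 ** rng.normal(
            params.response_latency_log10_mean, params.response_latency_log10_sd
        )

    next_base = {b: gap(b) for b in birds}
    responses: dict[str, list[float]] = {b: [] for b in birds}
    last_offset = {b: -math.inf for b in birds}
    events: list[CallEvent] = []

    while True:
        best: tuple[float, int, bool] | None = None  # (time, bird index, is_response)
        for i, b in enumerate(birds):
            if responses[b]:
                t_resp = min(responses[b])
                if best is None or t_resp < best[0]:
                    best = (t_resp, i, True)
            if next_base[b] < (best[0] if best else math.inf):
                best = (next_base[b], i, False)
        if best is None:
            break
        t, i, is_response = best
        bird = birds[i]
        if not math.isfinite(t) or t + dur > params.phase_duration:
            break
        # listen-before-call: no onset lands inside the partner's ongoing
        # call; it is deferred to the partner's offset
        blocking = [
            last_offset[o]
            for o in birds
            if o != bird and last_offset[o] - dur <= t < last_offset[o]
        ]
        if is_response:
            responses[bird].remove(t)
            if t < last_offset[bird] + params.refractory:
                continue  # suppressed: bird is still in its refractory window
            if blocking:
                responses[bird].append(max(blocking))
                continue
        else:
            if t < last_offset[bird] + params.refractory:
                next_base[bird] = last_offset[bird] + params.refractory
                continue
            if blocking:
                next_base[bird] = max(blocking)
                continue
        offset = t + dur
        events.append(
            CallEvent(
                session_id=session_id,
                phase=phase,
                caller_id=bird,
                onset=t,
                offset=offset,
                vocal_type=VocalType.CALL,
            )
        )
        last_offset[bird] = offset
        next_base[bird] = offset + gap(bird)
        for other in birds:
            if other != bird and rng.random() < params.response_prob:
                responses[other].append(offset + latency())
    return sorted(events)


def simulate_f2f_session(
    params: SimulationParams,
    session_id: str = "S1",
    subject: str = "A",
    facing: str = "B",
    rng: np.random.Generator | None = None,
    rate_multipliers: dict[str, float] | None = None,
) -> SessionRecord:
    """One face-to-face phase for a subject/facing pair."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    events = _simulate_tracks(
        params, [subject, facing], rng, session_id, Phase.F2F, rate_multipliers
    )
    return SessionRecord(session_id=session_id, pair=(subject, facing), events=events)


def simulate_solo_phase(
    params: SimulationParams,
    session_id: str = "S1",
    subject: str = "A",
    phase: Phase = Phase.PRE,
    rng: np.random.Generator | None = None,
    rate_multiplier: float = 1.0,
) -> SessionRecord:
    """A single-bird phase: spontaneous renewal calling only."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    events = _simulate_tracks(
        params, [subject], rng, session_id, phase, {subject: rate_multiplier}
    )
    return SessionRecord(session_id=session_id, pair=(subject, ""), events=events)


def simulate_experiment(
    params: SimulationParams,
    n_subjects: int = 6,
    sessions_per_pair: int = 4,
    phase_rate_multipliers: dict[Phase, float] | None = None,
    subject_rate_sd: float = 0.0,
    seed: int | None = None,
) -> list[SessionRecord]:
    """A full experiment: every pair of birds, several sessions each.

    With six birds this is 15 pairs x 4 sessions = 60 three-phase
    sessions.  The subject (first-introduced) role alternates between
    the two pair members across the pair's sessions.  Optional
    multipliers modulate calling rates per phase (e.g. elevated calling
    when a partner is visible) and per subject (log-normal individual
    effect with standard deviation ``subject_rate_sd``), for count-model
    recovery studies.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    phase_mult = {p: 1.0 for p in Phase}
    if phase_rate_multipliers:
        phase_mult.update(phase_rate_multipliers)
    birds = [f"B{i + 1}" for i in range(n_subjects)]
    bird_mult = {
        b: float(np.exp(rng.normal(0.0, subject_rate_sd))) if subject_rate_sd > 0 else 1.0
        for b in birds
    }
    sessions: list[SessionRecord] = []
    k = 0
    for a, b in combinations(birds, 2):
        for s in range(sessions_per_pair):
            k += 1
            subject, facing = (a, b) if s % 2 == 0 else (b, a)
            sid = f"S{k:03d}"
            events: list[CallEvent] = []
            for phase in (Phase.PRE, Phase.F2F, Phase.POST):
                mults = {
                    subject: bird_mult[subject] * phase_mult[phase],
                    facing: bird_mult[facing] * phase_mult[phase],
                }
                if phase is Phase.F2F:
                    events += _simulate_tracks(
                        params, [subject, facing], rng, sid, phase, mults
                    )
                else:
                    events += _simulate_tracks(params, [subject], rng, sid, phase, mults)
            sessions.append(
                SessionRecord(session_id=sid, pair=(subject, facing), events=events)
            )
    return sessions


def fixture_sessions(seed: int = 12345, n_subjects: int = 4, sessions_per_pair: int = 2):
    """A small deterministic dataset for tests and demos."""
    params = replace(SimulationParams(), seed=seed)
    return simulate_experiment(
        params,
        n_subjects=n_subjects,
        sessions_per_pair=sessions_per_pair,
        phase_rate_multipliers={Phase.F2F: 1.5},
        seed=seed,
    )
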