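"""Inter-annotator validation: agreement rate and timing-bias checks.

Two independent annotators segment and label the same recording; their
label sets are matched segment-to-segment, the joint classification +
caller agreement rate is reported, and onset/offset time differences
between matched segments are tested for systematic bias with a
one-sample t confidence interval (an interval excluding zero means one
annotator systematically places boundaries earlier than the other).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .events_io import CallEvent

#: Maximum onset discrepancy (s) for two annotations to describe the
#: same vocalization.  Annotator disagreement on boundaries is on the
#: order of milliseconds; 0.5 s is generous.
MATCH_WINDOW = 0.5


@dataclass(frozen=True)
class AgreementResult:
    n_all: int
    n_agree: int
    onset_delta_ci: tuple[float, float]
    offset_delta_ci: tuple[float, float]

    @property
    def accuracy(self) -> float:
        return agreement_accuracy(self.n_agree, self.n_all)

    @property
    def onset_biased(self) -> bool:
        lo, hi = self.onset_delta_ci
        return not lo <= 0.0 <= hi

    @property
    def offset_biased(self) -> bool:
        lo, hi = self.offset_delta_ci
        return not lo <= 0.0 <= hi

    def report(self) -> str:
        return (
            f"segments compared: {self.n_all}; agreements: {self.n_agree}; "
            f"accuracy: {100 * self.accuracy:.2f}%\n"
            f"onset  delta 95% CI: [{self.onset_delta_ci[0]:.3f}, {self.onset_delta_ci[1]:.3f}] s "
            f"({'biased' if self.onset_biased else 'no bias'})\n"
            f"offset delta 95% CI: [{self.offset_delta_ci[0]:.3f}, {self.offset_delta_ci[1]:.3f}] s "
            f"({'biased' if self.offset_biased else 'no bias'})"
        )


def agreement_accuracy(n_agree: int, n_all: int) -> float:
    """Raw agreement rate n_agree / n_all (no chance correction)."""
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if not 0 <= n_agree <= n_all:
        raise ValueError("need 0 <= n_agree <= n_all")
    return n_agree / n_all


def nearest_neighbor_deltas(
    times_a: Sequence[float], times_b: Sequence[float]
) -> np.ndarray:
    """For each time in ``a``, signed offset to its nearest time in ``b``.

    Delta = t_a - nearest(t_b); an exact distance tie resolves to the
    earlier neighbor.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.sort(np.asarray(times_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both time lists must be non-empty")
    idx = np.searchsorted(b, a)
    left = np.clip(idx - 1, 0, b.size - 1)
    right = np.clip(idx, 0, b.size - 1)
    # ties (equal distance) go to the earlier neighbor, hence <=
    pick_left = np.abs(a - b[left]) <= np.abs(b[right] - a)
    nearest = np.where(pick_left, b[left], b[right])
    return a - nearest


def one_sample_mean_ci(
    deltas: Sequence[float], level: float = 95.0
) -> tuple[float, float]:
    """Student-t confidence interval for the mean of the deltas."""
    x = np.asarray(deltas, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a t interval")
    mean = float(x.mean())
    if np.ptp(x) == 0:
        return (mean, mean)  # degenerate: constant deltas
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    half = stats.t.ppf(1.0 - (100.0 - level) / 200.0, df=x.size - 1) * sem
    return (mean - half, mean + half)


def match_events(
    events_a: Sequence[CallEvent],
    events_b: Sequence[CallEvent],
    window: float = MATCH_WINDOW,
) -> list[tuple[CallEvent, CallEvent]]:
    """Greedy one-to-one matching of two annotations by nearest onset.

    Candidate pairs within ``window`` seconds are taken closest-first;
    each segment is used at most once.  Unmatched segments have no
    counterpart and count as disagreements downstream.
    """
    candidates = [
        (abs(ea.onset - eb.onset), i, j)
        for i, ea in enumerate(events_a)
        for j, eb in enumerate(events_b)
        if abs(ea.onset - eb.onset) <= window
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((events_a[i], events_b[j]))
    return matches


def validate_labelling(
    events_a: Sequence[CallEvent],
    events_b: Sequence[CallEvent],
    window: float = MATCH_WINDOW,
    level: float = 95.0,
) -> AgreementResult:
    """Full validation of annotator A against annotator B.

    A matched pair agrees when vocal type AND caller assignment are both
    identical.  ``n_all`` counts every distinct segmented region: each
    matched pair once, plus every unmatched segment from either side.
    """
    matches = match_events(events_a, events_b, window=window)
    n_all = len(events_a) + len(events_b) - len(matches)
    n_agree = sum(
        1
        for ea, eb in matches
        if ea.vocal_type is eb.vocal_type and ea.caller_id == eb.caller_id
    )
    if len(matches) >= 2:
        onset_ci = one_sample_mean_ci([ea.onset - eb.onset for ea, eb in matches], level)
        offset_ci = one_sample_mean_ci([ea.offset - eb.offset for ea, eb in matches], level)
    else:
        onset_ci = offset_ci = (float("nan"), float("nan"))
    return AgreementResult(
        n_all=n_all,
        n_agree=n_agree,
        onset_delta_ci=onset_ci,
        offset_delta_ci=offset_ci,
    )
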