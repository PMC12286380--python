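"""Two-component Gaussian-mixture decomposition of log inter-call intervals.

Inter-call intervals in exchanging animals are classically bimodal on a
log scale: a *short* component of latencies from one call triggering the
next, and a *long* component of gaps between independently produced
calls.  The decomposition here log-transforms intervals (base 10, so
that an antilogged component mean reads directly in seconds), drops
non-positive intervals (overlaps, where no log exists), and fits a
two-component unequal-variance Gaussian mixture by expectation-
maximization.  Components are labelled so that ``mean_short <
mean_long``; the number of components is fixed at two by design, not
selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

#: Floor on component variances, in (log10 s)^2; prevents a component
#: collapsing onto duplicated values.
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class GmmFit:
    """Fitted two-component mixture over log-transformed intervals."""

    n_used: int
    n_excluded_nonpositive: int
    mean_short: float
    mean_long: float
    var_short: float
    var_long: float
    weight_short: float
    weight_long: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        assert self.mean_short <= self.mean_long
        assert abs(self.weight_short + self.weight_long - 1.0) < 1e-9
        assert self.var_short > 0 and self.var_long > 0

    def component(self, name: str) -> tuple[float, float, float]:
        """(mean, variance, weight) of the named component."""
        if name == "short":
            return self.mean_short, self.var_short, self.weight_short
        if name == "long":
            return self.mean_long, self.var_long, self.weight_long
        raise ValueError(f"unknown component {name!r}")


def log_transform_intervals(
    intervals: Sequence[float], base: float = 10.0
) -> tuple[np.ndarray, int]:
    """Drop non-positive intervals, log-transform the rest.

    Returns the transformed values and the count of excluded intervals.
    Overlapping calls produce negative intervals, which have no
    logarithm; a zero interval (offset exactly meeting the next onset)
    is likewise excluded.
    """
    if base <= 1:
        raise ValueError("log base must exceed 1")
    arr = np.asarray(intervals, dtype=float)
    keep = arr > 0
    values = np.log(arr[keep]) / np.log(base)
    return values, int((~keep).sum())


def antilog_mean(mean: float, base: float = 10.0) -> float:
    """Back-transform a log-scale mean to seconds, at report precision."""
    if base <= 1:
        raise ValueError("log base must exceed 1")
    return round(float(base**mean), 3)


def fit_two_component_gmm(
    values: Sequence[float],
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 5000,
    n_excluded_nonpositive: int = 0,
) -> GmmFit:
    """Maximum-likelihood two-component Gaussian mixture on log intervals.

    EM with unequal variances, best of ``n_restarts`` initializations by
    log-likelihood, deterministic given ``seed``.  Components are
    relabelled after the fit so the short (smaller-mean) component comes
    first.  Raises for fewer than four values (two per component) or a
    degenerate all-identical sample.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 4:
        raise ValueError(f"need at least 4 values to fit two components, got {x.shape[0]}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all values identical (zero variance)")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        reg_covar=VARIANCE_FLOOR,
        max_iter=max_iter,
        n_init=n_restarts,
        init_params="kmeans",
        random_state=seed,
    ).fit(x)
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    order = np.argsort(means)  # short first
    (m_s, m_l), (v_s, v_l), (w_s, w_l) = means[order], variances[order], weights[order]
    return GmmFit(
        n_used=int(x.shape[0]),
        n_excluded_nonpositive=n_excluded_nonpositive,
        mean_short=float(m_s),
        mean_long=float(m_l),
        var_short=float(v_s),
        var_long=float(v_l),
        weight_short=float(w_s),
        weight_long=float(w_l),
        loglik=float(gm.score(x) * x.shape[0]),
        converged=bool(gm.converged_),
    )


def fit_intervals(
    intervals: Sequence[float],
    seed: int = 0,
    base: float = 10.0,
    n_restarts: int = 10,
    tol: float = 1e-8,
) -> GmmFit:
    """Log-transform raw second-valued intervals and fit the mixture."""
    values, n_excluded = log_transform_intervals(intervals, base=base)
    return fit_two_component_gmm(
        values,
        seed=seed,
        n_restarts=n_restarts,
        tol=tol,
        n_excluded_nonpositive=n_excluded,
    )


def fits_to_table(fits: dict[str, GmmFit], base: float = 10.0) -> pd.DataFrame:
    """Summary table: one row per (condition, component), antilogs included."""
    rows = []
    for name, fit in fits.items():
        for comp in ("short", "long"):
            mean, var, weight = fit.component(comp)
            rows.append(
                {
                    "transition": name,
                    "n": fit.n_used,
                    "component": comp,
                    "mean": round(mean, 3),
                    "antilog_mean": antilog_mean(mean, base),
                    "variance": round(var, 3),
                    "mixture_ratio": round(weight, 3),
                }
            )
    return pd.DataFrame(rows)
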