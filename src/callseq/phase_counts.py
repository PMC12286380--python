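"""Phase-wise call counts and Poisson mixed-effects model selection.

Does a bird call more when a partner is present?  The subject's calls
are counted per (subject, trial, phase) cell and modelled with a
Poisson log-link GLMM: experimental phase as the fixed effect (solo-
before as the reference level, so the face-to-face and solo-after
coefficients are log rate ratios), and independent Gaussian random
intercepts for subject and trial.  The phase model is compared with the
matching null model (random intercepts only) by AIC.

The marginal likelihood is Laplace-approximated: for candidate variance
parameters, the joint conditional mode of the fixed effects and random
intercepts is found by Newton iteration on the penalized Poisson
log-likelihood, and the random-effect block of the Hessian supplies the
Gaussian curvature correction.  This is the same approximation the
standard mixed-model fitters use by default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from .events_io import Phase, SessionRecord, VocalType


@dataclass(frozen=True)
class PhaseCountRow:
    subject_id: str
    trial_id: str
    phase: Phase
    n_calls: int

    def __post_init__(self) -> None:
        if self.n_calls < 0 or int(self.n_calls) != self.n_calls:
            raise ValueError(f"n_calls must be a non-negative integer, got {self.n_calls}")


@dataclass
class CountModelFit:
    """A fitted Poisson GLMM (or its null) with AIC bookkeeping."""

    fixed_effects: dict[str, float]
    random_intercept_variances: dict[str, float]
    loglik: float
    n_parameters: int
    singular: bool
    converged: bool
    include_phase: bool
    data_fingerprint: tuple = field(repr=False, default=())

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_parameters


def count_calls_by_phase(sessions: list[SessionRecord]) -> list[PhaseCountRow]:
    """One row per (subject, trial, phase): the subject's call count.

    The trial is the session; calls by the facing bird never count
    toward the subject's cell.
    """
    rows = []
    for rec in sessions:
        for phase in Phase:
            n = sum(
                1
                for ev in rec.events_in(phase)
                if ev.caller_id == rec.subject and ev.vocal_type is VocalType.CALL
            )
            rows.append(
                PhaseCountRow(
                    subject_id=rec.subject,
                    trial_id=rec.session_id,
                    phase=phase,
                    n_calls=n,
                )
            )
    return rows


def counts_to_frame(rows: list[PhaseCountRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "trial_id": r.trial_id,
                "phase": r.phase.value,
                "n_calls": r.n_calls,
            }
            for r in rows
        ]
    )


def _fingerprint(rows: list[PhaseCountRow]) -> tuple:
    return tuple(
        sorted((r.subject_id, r.trial_id, r.phase.value, r.n_calls) for r in rows)
    )


def _design(rows: list[PhaseCountRow], include_phase: bool):
    subjects = sorted({r.subject_id for r in rows})
    trials = sorted({r.trial_id for r in rows})
    n = len(rows)
    fixed_names = ["(Intercept)"] + (
        ["phase[F2F]", "phase[POST]"] if include_phase else []
    )
    X = np.zeros((n, len(fixed_names)))
    X[:, 0] = 1.0
    if include_phase:
        for i, r in enumerate(rows):
            if r.phase is Phase.F2F:
                X[i, 1] = 1.0
            elif r.phase is Phase.POST:
                X[i, 2] = 1.0
    Z = np.zeros((n, len(subjects) + len(trials)))
    s_index = {s: j for j, s in enumerate(subjects)}
    t_index = {t: len(subjects) + j for j, t in enumerate(trials)}
    for i, r in enumerate(rows):
        Z[i, s_index[r.subject_id]] = 1.0
        Z[i, t_index[r.trial_id]] = 1.0
    y = np.array([r.n_calls for r in rows], dtype=float)
    return X, Z, y, fixed_names, len(subjects), len(trials)


def _joint_mode(X, Z, y, d_inv, max_iter=200, tol=1e-10):
    """Newton maximization of the u-penalized Poisson log-likelihood.

    Returns (beta, u, penalized loglik at mode, u-block Hessian).
    """
    n, p = X.shape
    q = Z.shape[1]
    M = np.hstack([X, Z])
    gamma = np.zeros(p + q)
    gamma[0] = math.log(max(y.mean(), 1e-3))
    pen = np.concatenate([np.zeros(p), d_inv])

    def objective(g):
        eta = np.clip(M @ g, -30, 30)
        return float(y @ eta - np.exp(eta).sum() - 0.5 * np.sum(pen * g * g))

    obj = objective(gamma)
    for _ in range(max_iter):
        eta = np.clip(M @ gamma, -30, 30)
        mu = np.exp(eta)
        grad = M.T @ (y - mu) - pen * gamma
        H = (M.T * mu) @ M
        H[np.diag_indices_from(H)] += pen
        step = np.linalg.solve(H, grad)
        t = 1.0
        while t > 1e-8:
            cand = gamma + t * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t /= 2.0
        gamma, new_obj = gamma + t * step, objective(gamma + t * step)
        if abs(new_obj - obj) < tol * (abs(obj) + 1.0):
            obj = new_obj
            break
        obj = new_obj
    eta = np.clip(M @ gamma, -30, 30)
    mu = np.exp(eta)
    H_uu = (Z.T * mu) @ Z
    H_uu[np.diag_indices_from(H_uu)] += d_inv
    return gamma[:p], gamma[p:], eta, H_uu


_LOGVAR_BOUNDS = (-12.0, 6.0)
_SINGULAR_VAR = 1e-4


def _laplace_loglik(theta, X, Z, y, n_subj, n_trial):
    """Laplace-approximated marginal log-likelihood at log-variances theta."""
    v = np.exp(np.clip(theta, *_LOGVAR_BOUNDS))
    d = np.concatenate([np.full(n_subj, v[0]), np.full(n_trial, v[1])])
    beta, u, eta, H_uu = _joint_mode(X, Z, y, 1.0 / d)
    mu = np.exp(eta)
    cond_ll = float(y @ eta - mu.sum() - gammaln(y + 1.0).sum())
    sign, logdet_H = np.linalg.slogdet(H_uu)
    if sign <= 0:
        return -np.inf, beta, u
    ll = cond_ll - 0.5 * float(u * (1.0 / d) @ u) - 0.5 * float(np.log(d).sum()) - 0.5 * logdet_H
    return ll, beta, u


def fit_count_model(rows: list[PhaseCountRow], include_phase: bool = True) -> CountModelFit:
    """Fit the Poisson GLMM (phase fixed effect optional) by Laplace ML.

    Requires at least two subjects and two trials.  A fit whose
    random-effect variance collapses to (numerical) zero is flagged
    singular but still returned.
    """
    X, Z, y, fixed_names, n_subj, n_trial = _design(rows, include_phase)
    if n_subj < 2 or n_trial < 2:
        raise ValueError("need at least 2 subjects and 2 trials")

    def neg_ll(theta):
        ll, _, _ = _laplace_loglik(theta, X, Z, y, n_subj, n_trial)
        return -ll

    res = optimize.minimize(
        neg_ll,
        x0=np.array([math.log(0.1), math.log(0.1)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
    )
    theta = np.clip(res.x, *_LOGVAR_BOUNDS)
    ll, beta, _ = _laplace_loglik(theta, X, Z, y, n_subj, n_trial)
    variances = {"subject": float(np.exp(theta[0])), "trial": float(np.exp(theta[1]))}
    return CountModelFit(
        fixed_effects=dict(zip(fixed_names, map(float, beta))),
        random_intercept_variances=variances,
        loglik=float(ll),
        n_parameters=len(fixed_names) + 2,
        singular=any(v < _SINGULAR_VAR for v in variances.values()),
        converged=bool(res.success or res.fun < np.inf),
        include_phase=include_phase,
        data_fingerprint=_fingerprint(rows),
    )


class AicTie(enum.Enum):
    NONE = "none"
    TIED = "tied"


def select_model_aic(fits: list[CountModelFit]) -> tuple[CountModelFit, pd.DataFrame]:
    """Pick the minimum-AIC fit; return it with a delta-AIC table.

    All candidate fits must have been fitted to the same rows.  Exact
    ties go to the first fit in input order and are recorded in the
    table's ``tied`` column.
    """
    if not fits:
        raise ValueError("no fits supplied")
    fingerprints = {f.data_fingerprint for f in fits}
    if len(fingerprints) > 1:
        raise ValueError("fits were made on differing data; AICs are not comparable")
    aics = np.array([f.aic for f in fits])
    best_idx = int(np.argmin(aics))
    best_aic = aics[best_idx]
    table = pd.DataFrame(
        {
            "model": [
                "phase" if f.include_phase else "null" for f in fits
            ],
            "aic": aics,
            "delta_aic": aics - best_aic,
            "tied": [(a == best_aic) and (i != best_idx) for i, a in enumerate(aics)],
        }
    )
    return fits[best_idx], table
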