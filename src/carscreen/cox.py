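"""Univariate Cox-score comparator.

The conventional marginal screen for right-censored outcomes: fit a
single-covariate Cox proportional-hazards model per column and take the
standardized coefficient (Wald Z = β̂ / se(β̂)) as the score. Dependencies
between covariates are ignored, which is exactly the weakness the CARS
score addresses; the two screens share the ranking and selection machinery.

The partial likelihood is maximized by Newton–Raphson with the Breslow
approximation for tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .sample import SurvivalSample, as_sample
from .scoring import abs_ranks

#: |z| assigned when the partial likelihood is monotone (perfect separation)
Z_CAP = 37.0

_MAX_ITER = 50
_SCORE_TOL = 1e-9


@dataclass(frozen=True)
class CoxScoreVector:
    """Wald Z per covariate; ``converged`` flags clean Newton convergence."""

    z_scores: np.ndarray
    converged: np.ndarray

    @property
    def d(self) -> int:
        return self.z_scores.shape[0]


def _breslow_quantities(x, times, status):
    """Sort by time and precompute the index bookkeeping for risk sets.

    Returns (x sorted descending in time, event mask in that order,
    group boundaries) so that cumulative sums from the start give risk-set
    sums over {T̃_j >= t}. Ties share a risk set (Breslow).
    """
    order = np.argsort(-times, kind="stable")
    return x[order], times[order], status[order].astype(bool)


def _partial_loglik_terms(beta, xs, ts, ev):
    """Log-likelihood, score and information of the 1-parameter Cox model.

    Arrays are sorted by descending time; the risk set of an event at t is
    every index up to the last position with the same time (Breslow ties).
    """
    eta = beta * xs
    eta = eta - eta.max()  # overflow guard; cancels in the ratios
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs * xs)
    # extend each risk set through ties: use the last cumsum index with time == t
    last_eq = np.searchsorted(-ts, -ts, side="right") - 1
    s0e, s1e, s2e = s0[last_eq][ev], s1[last_eq][ev], s2[last_eq][ev]
    xbar = s1e / s0e
    # eta is uniformly shifted, which cancels between the two sums
    loglik = float(np.sum(eta[ev]) - np.sum(np.log(s0e)))
    score = float(np.sum(xs[ev] - xbar))
    info = float(np.sum(s2e / s0e - xbar**2))
    return loglik, score, info


def cox_partial_loglik(beta: float, x, times, status) -> float:
    """Breslow partial log-likelihood at ``beta`` (up to the eta-shift constant).

    Exposed for brute-force verification; the shift by max(η) is a constant
    offset per dataset and does not affect comparisons in β.
    """
    x = np.asarray(x, dtype=float)
    xs, ts, ev = _breslow_quantities(x, np.asarray(times, float), np.asarray(status))
    return _partial_loglik_terms(float(beta), xs, ts, ev)[0]


def univariate_cox_fit(x, times, status):
    """Newton–Raphson fit of the single-covariate Cox model.

    Breslow ties, at most 50 iterations, convergence when the score drops
    below 1e−9. Returns ``(beta_hat, se, converged)`` on the original scale
    of ``x``; a monotone likelihood (no finite maximizer, e.g. perfect
    separation of risk sets) reports ``converged=False`` with the diverging
    sign encoded in ``beta_hat = ±inf``.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if status.sum() < 1:
        raise ValueError("need at least one event")
    if np.ptp(x) == 0:
        return 0.0, np.inf, True

    xs, ts, ev = _breslow_quantities(x, times, status)
    sd = x.std()
    xs = xs / sd  # z is scale-invariant; scaling keeps Newton well conditioned
    beta = 0.0
    diverged = None
    for _ in range(_MAX_ITER):
        _, score, info = _partial_loglik_terms(beta, xs, ts, ev)
        # a monotone likelihood drives beta out until the score underflows,
        # so a huge beta (per sd of x) means divergence, not convergence
        if abs(beta) > 15.0:
            diverged = np.sign(beta)
            break
        if abs(score) < _SCORE_TOL:
            break
        if info <= 0 or not np.isfinite(score):
            diverged = np.sign(score if np.isfinite(score) else beta)
            break
        beta += np.clip(score / info, -5.0, 5.0)  # dampen huge steps
    else:
        diverged = np.sign(beta)
    if diverged is not None:
        return float(diverged) * np.inf, np.nan, False
    _, _, info = _partial_loglik_terms(beta, xs, ts, ev)
    if info <= 0:
        return float(np.sign(beta)) * np.inf, np.nan, False
    return beta / sd, 1.0 / (np.sqrt(info) * sd), True


def univariate_cox_score(x, times, status):
    """Wald Z (= β̂ / se) of a single-covariate Cox fit.

    A constant covariate scores 0; a monotone likelihood returns
    ``converged=False`` and z capped at sign × 37.
    """
    beta, se, converged = univariate_cox_fit(x, times, status)
    if not converged:
        return float(np.sign(beta)) * Z_CAP, False
    if not np.isfinite(se):  # constant covariate
        return 0.0, True
    return float(beta / se), True


def cox_scores(sample: SurvivalSample) -> CoxScoreVector:
    """Apply :func:`univariate_cox_score` to every covariate column."""
    z = np.empty(sample.d)
    conv = np.empty(sample.d, dtype=bool)
    for j in range(sample.d):
        z[j], conv[j] = univariate_cox_score(
            sample.covariates[:, j], sample.times, sample.status
        )
    return CoxScoreVector(z, conv)


class CoxScorer(BaseEstimator):
    """Univariate Cox screening estimator (the baseline CARS is compared to).

    ``fit(X, y)`` computes one Wald Z per column of X against the survival
    target ``y`` (structured array with ``event``/``time`` fields or a
    ``(times, status)`` pair).

    Attributes
    ----------
    scores_ : ndarray of shape (d,)
        Standardized univariate Cox coefficients (Wald Z).
    converged_ : ndarray of bool, shape (d,)
        False where the likelihood was monotone and the score was capped.
    ranks_ : ndarray of shape (d,)
        1 = largest \\|Z\\|.
    """

    def fit(self, X, y):
        sample = as_sample(X, y, getattr(X, "columns", None))
        res = cox_scores(sample)
        self.result_ = res
        self.scores_ = res.z_scores
        self.converged_ = res.converged
        self.ranks_ = abs_ranks(res.z_scores)
        self.n_features_in_ = sample.d
        self.feature_names_in_ = np.asarray(sample.covariate_names, dtype=object)
        return self
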