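"""Adaptive false-discovery-rate selection on score vectors.

Signed scores (CARS or Cox) are symmetrized to absolute values and modelled
as a two-component mixture: a proportion ``eta0`` of "noninfluential"
covariates whose |score| follows a half-normal null with scale σ, and the
rest "influential". The null is fitted by truncated maximum likelihood —
only scores below a truncation point, chosen on a quantile grid by
Kolmogorov distance, inform the fit — and the empirical distribution is
smoothed by its least concave majorant (the Grenander construction for a
decreasing density). Tail-area q-values

    q(s) = min over thresholds t ≤ s of  c_d · eta0 · F̄_null(t) / F̄_emp(t)

are clipped to [0, 1]; the running minimum makes them monotone
(non-decreasing as |score| decreases). ``c_d = Σ_{i≤d} 1/i`` is the
harmonic dependence correction of Benjamini–Yekutieli: the score vectors
being thresholded here are mutually dependent by construction (correlated
covariates yield correlated screening statistics), and the plain tail-area
ratio is anti-conservative for the extreme order statistics under
dependence. A covariate is selected when its q-value falls below the user
threshold α₁.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "MixtureFit",
    "fit_null_halfnormal",
    "q_values_from_fit",
    "select_markers",
    "FDRSelector",
]

MIN_SCORES_FOR_FIT = 20
_GRID_PERCENTILES = np.arange(50, 100, 5)  # 50th .. 95th


@dataclass(frozen=True)
class MixtureFit:
    """Fitted two-component mixture over absolute scores."""

    eta0: float
    null_scale: float
    local_fdr: np.ndarray
    q_values: np.ndarray
    truncation_point: float


def _halfnormal_cdf(s, scale):
    return special.erf(np.asarray(s, dtype=float) / (scale * np.sqrt(2.0)))


def _halfnormal_sf(s, scale):
    return special.erfc(np.asarray(s, dtype=float) / (scale * np.sqrt(2.0)))


def _halfnormal_pdf(s, scale):
    s = np.asarray(s, dtype=float)
    return np.sqrt(2.0 / np.pi) / scale * np.exp(-(s**2) / (2.0 * scale**2))


def _truncated_ml_scale(sub: np.ndarray, trunc: float) -> float:
    """ML scale of a half-normal truncated to [0, trunc], fitted to ``sub``."""
    ss = float(np.mean(sub**2))

    def neg_loglik(log_sigma):
        sigma = np.exp(log_sigma)
        f_t = _halfnormal_cdf(trunc, sigma)
        return ss / (2.0 * sigma**2) + log_sigma + np.log(max(f_t, 1e-300))

    res = optimize.minimize_scalar(
        neg_loglik,
        bounds=(np.log(max(np.sqrt(ss), 1e-12) / 10), np.log(10 * trunc)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def _lcm_cdf(points_x: np.ndarray, points_y: np.ndarray):
    """Least concave majorant of a CDF given as points; returns hull vertices.

    Upper convex hull over x-sorted points; the slopes of the resulting
    piecewise-linear CDF are the Grenander decreasing density.
    """
    hull_x = [points_x[0]]
    hull_y = [points_y[0]]
    for x, y in zip(points_x[1:], points_y[1:]):
        while len(hull_x) >= 2:
            cross = (hull_x[-1] - hull_x[-2]) * (y - hull_y[-2]) - (
                hull_y[-1] - hull_y[-2]
            ) * (x - hull_x[-2])
            if cross >= 0:  # middle point below the chord: not on the majorant
                hull_x.pop()
                hull_y.pop()
            else:
                break
        hull_x.append(x)
        hull_y.append(y)
    return np.asarray(hull_x), np.asarray(hull_y)


def _grenander(abs_scores: np.ndarray):
    """Grenander-smoothed CDF and density evaluators for |scores|."""
    s = np.sort(np.asarray(abs_scores, dtype=float))
    n = s.size
    x = np.concatenate([[0.0], s])
    y = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    # collapse ties on x: keep the highest CDF value at each distinct point
    x_uniq, last_idx = np.unique(x[::-1], return_index=True)
    y_uniq = y[::-1][last_idx]
    hx, hy = _lcm_cdf(x_uniq, y_uniq)

    def cdf(q):
        return np.interp(np.asarray(q, dtype=float), hx, hy, left=0.0, right=1.0)

    slopes = np.diff(hy) / np.diff(hx) if hx.size > 1 else np.array([0.0])

    def pdf(q):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        idx = np.clip(np.searchsorted(hx, q, side="right") - 1, 0, slopes.size - 1)
        out = slopes[idx]
        out[q > hx[-1]] = 0.0
        return out

    return cdf, pdf


def fit_null_halfnormal(abs_scores: np.ndarray):
    """Fit the half-normal null component by truncated maximum likelihood.

    Candidate truncation points are the 50th–95th percentiles of |scores|
    (step 5). For each candidate, the half-normal scale is fitted by ML on
    the scores below it, the implied null proportion is
    ``eta0 = min(1, (#below / d) / F_null(truncation))``, and the
    Kolmogorov distance between the implied null CDF ``eta0 · F_null`` and
    the empirical CDF is measured over the common span up to the largest
    candidate; the smallest candidate attaining the minimal distance wins.
    Judging all candidates on the same span is essential: the lower half of
    a half-normal only weakly identifies its scale, so a candidate's fit to
    its own truncated subsample always looks deceptively good.

    Returns ``(null_scale, eta0, truncation_point)``.
    """
    s = np.abs(np.asarray(abs_scores, dtype=float))
    d = s.size
    if d < MIN_SCORES_FOR_FIT:
        raise ValueError(
            f"mixture fitting needs at least {MIN_SCORES_FOR_FIT} scores (got {d}); "
            "use a direct |score| threshold instead"
        )
    if np.ptp(s) == 0:
        # degenerate: no spread, everything is null
        return max(float(s[0]), 1e-12), 1.0, max(float(s[0]), 1e-12)

    candidates = np.percentile(s, _GRID_PERCENTILES)
    tau_max = candidates[-1]
    ref = np.sort(s[s <= tau_max])
    emp_hi = np.arange(1, ref.size + 1) / d
    emp_lo = np.arange(0, ref.size) / d
    best = None
    for trunc in candidates:
        sub = np.sort(s[s <= trunc])
        if sub.size < 3 or trunc <= 0 or np.ptp(sub) == 0:
            continue
        sigma = _truncated_ml_scale(sub, trunc)
        eta0 = min(1.0, (sub.size / d) / max(_halfnormal_cdf(trunc, sigma), 1e-300))
        pred = eta0 * _halfnormal_cdf(ref, sigma)
        ks = float(np.max(np.maximum(np.abs(pred - emp_hi), np.abs(pred - emp_lo))))
        if best is None or ks < best[0] - 1e-12:
            best = (ks, float(trunc), sigma, eta0)
    if best is None:
        return max(float(np.max(s)), 1e-12), 1.0, max(float(np.max(s)), 1e-12)
    _, trunc, sigma, eta0 = best
    return sigma, eta0, trunc


def q_values_from_fit(
    abs_scores: np.ndarray, fit: MixtureFit, dependence_correction: bool = True
) -> np.ndarray:
    """Tail-area q-values from a fitted null (see module docstring).

    ``dependence_correction`` applies the harmonic factor ``Σ_{i≤d} 1/i``
    that keeps the false-discovery rate controlled under arbitrary
    dependence between the scores; disable it only for scores known to be
    independent.
    """
    s = np.abs(np.asarray(abs_scores, dtype=float))
    d = s.size
    c_d = float(np.sum(1.0 / np.arange(1, d + 1))) if dependence_correction else 1.0
    cdf_emp, _ = _grenander(s)
    sf_emp = np.maximum(1.0 - cdf_emp(s), 0.5 / d)
    ratio = np.clip(
        c_d * fit.eta0 * _halfnormal_sf(s, fit.null_scale) / sf_emp, 0.0, 1.0
    )
    # q(s) = min over thresholds t <= s: running minimum in ascending order
    order = np.argsort(s, kind="stable")
    q = np.empty(d)
    q[order] = np.minimum.accumulate(ratio[order])
    return q


def _mixture_fit(scores: np.ndarray) -> MixtureFit:
    s = np.abs(np.asarray(scores, dtype=float))
    null_scale, eta0, trunc = fit_null_halfnormal(s)
    partial = MixtureFit(eta0, null_scale, np.empty(0), np.empty(0), trunc)
    q = q_values_from_fit(s, partial)
    _, pdf_emp = _grenander(s)
    dens = np.maximum(pdf_emp(s), 1e-300)
    lfdr = np.clip(eta0 * _halfnormal_pdf(s, null_scale) / dens, 0.0, 1.0)
    return MixtureFit(eta0, null_scale, lfdr, q, trunc)


def select_markers(scores: np.ndarray, alpha1: float):
    """Select covariates whose q-value is below ``alpha1``.

    Returns ``(selected boolean vector, MixtureFit)``.
    """
    if not 0.0 < alpha1 < 1.0:
        raise ValueError("alpha1 must lie in (0, 1)")
    fit = _mixture_fit(scores)
    return fit.q_values < alpha1, fit


class FDRSelector(SelectorMixin, BaseEstimator):
    """Feature selector: score covariates, then threshold their q-values.

    Wraps a scoring estimator (by default :class:`~carscreen.scoring.CARSScorer`)
    and keeps the columns whose mixture-model q-value is below ``alpha1``.
    Works as a step in a scikit-learn ``Pipeline``.

    Parameters
    ----------
    scorer : estimator or None
        Any estimator exposing ``scores_`` after ``fit(X, y)``; ``None``
        means a fresh ``CARSScorer()``.
    alpha1 : float, default 0.05
        q-value selection threshold.

    Attributes
    ----------
    scores_, q_values_, support_ : ndarrays of shape (d,)
    mixture_fit_ : MixtureFit
    eta0_, null_scale_ : floats from the fitted null component
    """

    def __init__(self, scorer=None, alpha1=0.05):
        self.scorer = scorer
        self.alpha1 = alpha1

    def fit(self, X, y):
        from .scoring import CARSScorer

        scorer = clone(self.scorer) if self.scorer is not None else CARSScorer()
        scorer.fit(X, y)
        self.scorer_ = scorer
        self.scores_ = np.asarray(scorer.scores_, dtype=float)
        selected, fit = select_markers(self.scores_, self.alpha1)
        self.mixture_fit_ = fit
        self.q_values_ = fit.q_values
        self.eta0_ = fit.eta0
        self.null_scale_ = fit.null_scale
        self.support_ = selected
        self.n_features_in_ = self.scores_.shape[0]
        return self

    def _get_support_mask(self):
        return self.support_
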