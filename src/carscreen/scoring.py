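"""Correlation-adjusted regression survival (CARS) scores.

The CARS score of covariate j is the correlation between the log survival
time and the j-th *decorrelated* covariate. At the population level, with
P_X the covariate correlation matrix and P_XY the vector of correlations
between the covariates and Y = log T,

    θ = P_X^{−1/2} P_XY ,

and θᵀθ is the share of Var(Y) explained by the best linear predictor. The
empirical version under right-censoring replaces P_XY by an IPC-weighted
correlation vector R_XY and P_X by the shrinkage estimator R_shrink:

    θ̂ = R_shrink^{−1/2} R_XY .

The weighted moments follow the printed estimators exactly: the weighted
mean and variance of log T̃ and the covariances S_{Xj,Y;w} use a 1/n
normalization, while the covariate variances S²_j use the usual n−1
divisor. This mixed normalization is preserved verbatim (it vanishes
asymptotically); in the uncensored single-covariate case it makes the score
equal to Pearson's r times √((n−1)/n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from sklearn.base import BaseEstimator

from .ipcw import DEFAULT_FLOOR_NU, compute_ipc_weights
from .sample import SurvivalSample, as_sample
from .shrinkage import build_shrink_op, shrinkage_intensity, standardize_columns

__all__ = [
    "CARSResult",
    "PopulationModel",
    "CARSScorer",
    "cars_scores",
    "population_cars",
    "weighted_mean_var_logT",
    "weighted_cov_vector",
    "marginal_correlations",
    "abs_ranks",
]


def weighted_mean_var_logT(sample: SurvivalSample, weights):
    """IPC-weighted mean and variance of the log observed times.

    Both use the 1/n normalization: ``Ȳ_w = (1/n) Σ w_i log T̃_i`` and
    ``S²_{Y;w} = (1/n) Σ w_i (log T̃_i − Ȳ_w)²``.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != sample.n:
        raise ValueError("weights length must equal n")
    if not np.any(w > 0):
        raise ValueError("no uncensored observations: all IPC weights are zero")
    n = sample.n
    y = sample.log_times
    ybar_w = float(w @ y) / n
    s2_yw = float(w @ (y - ybar_w) ** 2) / n
    return ybar_w, s2_yw


def weighted_cov_vector(sample: SurvivalSample, weights, ybar_w: float) -> np.ndarray:
    """IPC-weighted covariances ``S_{Xj,Y;w}``, one matrix-vector product.

    Column means X̄_j are the plain unweighted means (covariates are not
    affected by censoring).
    """
    w = np.asarray(weights, dtype=float)
    if not np.any(w > 0):
        raise ValueError("no uncensored observations: all IPC weights are zero")
    X = sample.covariates
    Xc = X - X.mean(axis=0)
    resid = w * (sample.log_times - ybar_w)
    return (Xc.T @ resid) / sample.n


def marginal_correlations(cov_vec, s2_x, s2_yw: float) -> np.ndarray:
    """Correlation vector R_XY = S_{Xj,Y;w} / √(S²_j · S²_{Y;w}).

    Values are clamped into [−1, 1] with a warning; the mixed 1/n vs n−1
    normalization can push small-sample ratios slightly outside.
    """
    cov_vec = np.asarray(cov_vec, dtype=float)
    s2_x = np.asarray(s2_x, dtype=float)
    if np.any(s2_x <= 0):
        raise ValueError("covariate variances must be positive")
    if s2_yw <= 0:
        raise ValueError("degenerate outcome: weighted variance of log T is zero")
    r = cov_vec / np.sqrt(s2_x * s2_yw)
    if np.any(np.abs(r) > 1.0):
        worst = float(np.max(np.abs(r)))
        warnings.warn(
            f"marginal correlation clamped to [-1, 1] (max |r| = {worst:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -1.0, 1.0)
    return r


def abs_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank by |score| descending; ties keep original column order."""
    order = np.argsort(-np.abs(scores), kind="stable")
    ranks = np.empty(scores.shape[0], dtype=int)
    ranks[order] = np.arange(1, scores.shape[0] + 1)
    return ranks


@dataclass(frozen=True)
class CARSResult:
    """Per-covariate CARS scores with bookkeeping.

    ``scores`` are the decorrelated correlations θ̂; ``abs_rank`` gives 1 to
    the largest |θ̂|; ``marginal_corr`` is R_XY before decorrelation;
    ``n_effective`` is the IPC weight sum.
    """

    scores: np.ndarray
    abs_rank: np.ndarray
    marginal_corr: np.ndarray
    lambda_used: float
    n_effective: float
    covariate_names: tuple = field(default=None)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite CARS score")
        object.__setattr__(self, "scores", s)

    @property
    def d(self) -> int:
        return self.scores.shape[0]


def cars_scores(
    sample: SurvivalSample,
    lambda_override: float | None = None,
    floor_nu: float = DEFAULT_FLOOR_NU,
    g_values=None,
) -> CARSResult:
    """Empirical CARS scores θ̂ = R_shrink^{−1/2} R_XY for one sample.

    Pipeline: censoring Kaplan–Meier → IPC weights → column standardization
    → shrinkage intensity λ → weighted moments of log T̃ → marginal
    correlation vector → whitening by R_shrink^{−1/2}. Deterministic given
    the input.

    Parameters
    ----------
    lambda_override : float, optional
        Force the shrinkage intensity instead of estimating it (λ = 1 makes
        the scores equal to the marginal correlations).
    g_values : array, optional
        Externally supplied Ĝ(T̃_i⁻ | x_i) evaluations (conditional
        censoring hook); bypasses the Kaplan–Meier step.
    """
    if sample.n_events < 1:
        raise ValueError("need at least one event")
    w = compute_ipc_weights(sample, floor_nu=floor_nu, g_values=g_values).weights

    Xs, _, sds = standardize_columns(sample.covariates)
    if lambda_override is None:
        lam = shrinkage_intensity(Xs) if sample.d >= 2 else 1.0
    else:
        if not 0.0 <= lambda_override <= 1.0:
            raise ValueError("lambda_override must lie in [0, 1]")
        lam = float(lambda_override)

    ybar_w, s2_yw = weighted_mean_var_logT(sample, w)
    cov_vec = weighted_cov_vector(sample, w, ybar_w)
    r_xy = marginal_correlations(cov_vec, sds**2, s2_yw)

    if lam == 1.0:
        theta = r_xy.copy()
    else:
        op = build_shrink_op(Xs, lam)
        theta = op.apply_inv_sqrt(r_xy)

    return CARSResult(
        scores=theta,
        abs_rank=abs_ranks(theta),
        marginal_corr=r_xy,
        lambda_used=lam,
        n_effective=float(np.sum(w)),
        covariate_names=sample.covariate_names,
    )


@dataclass(frozen=True)
class PopulationModel:
    """Population lognormal AFT model ``log T = β₀ + xᵀβ + ε``.

    x ~ (μ, Σ) with ε ~ N(0, σ_ε²) independent of x. Under this model the
    covariance vector between x and Y = log T is Σβ, so the population CARS
    score has the closed form θ = P_X^{−1/2} P_XY.
    """

    Sigma: np.ndarray
    beta: np.ndarray
    beta0: float = 0.0
    sigma_eps2: float = 1.0

    def __post_init__(self):
        S = np.asarray(self.Sigma, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if S.shape[0] != S.shape[1] or S.shape[0] != b.shape[0]:
            raise ValueError("Sigma must be d x d matching beta")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be positive")
        try:
            cholesky(S, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover - scipy raises its own
            raise ValueError("Sigma is not positive definite") from e
        except Exception as e:
            raise ValueError("Sigma is not positive definite") from e
        object.__setattr__(self, "Sigma", S)
        object.__setattr__(self, "beta", b)

    @property
    def var_y(self) -> float:
        """Total variance σ_Y² = βᵀΣβ + σ_ε²."""
        return float(self.beta @ self.Sigma @ self.beta) + self.sigma_eps2

    def car_scores(self) -> np.ndarray:
        return population_cars(self)

    def explained_variance(self) -> float:
        """θᵀθ, the explained share of Var(log T)."""
        theta = population_cars(self)
        return float(theta @ theta)


def population_cars(model: PopulationModel) -> np.ndarray:
    """Closed-form population CARS score θ = P_X^{−1/2} P_XY.

    Valid for the lognormal AFT case, where Σ_XY = Σβ exactly. Uses a dense
    symmetric inverse square root (population d is small by construction).
    """
    Sigma, beta = model.Sigma, model.beta
    sd_x = np.sqrt(np.diag(Sigma))
    sigma_y = np.sqrt(model.var_y)
    p_xy = (Sigma @ beta) / (sd_x * sigma_y)
    P_X = Sigma / np.outer(sd_x, sd_x)
    evals, evecs = np.linalg.eigh(P_X)
    if evals.min() <= 0:
        raise ValueError("correlation matrix implied by Sigma is not positive definite")
    return (evecs / np.sqrt(evals)) @ (evecs.T @ p_xy)


class CARSScorer(BaseEstimator):
    """Ranks covariates against a right-censored outcome by CARS score.

    A univariate-screening estimator in the scikit-learn mold: ``fit(X, y)``
    with ``y`` a structured array carrying ``event`` and ``time`` fields (or
    a ``(times, status)`` pair) computes one score per column of X.

    Parameters
    ----------
    lambda_override : float or None, default None
        Fix the shrinkage intensity of the correlation estimator; ``None``
        estimates it from the data.
    floor_nu : float, default 1e-8
        Positivity floor for the estimated censoring survival function.

    Attributes
    ----------
    scores_ : ndarray of shape (d,)
        CARS scores θ̂ (signed; rank by absolute value).
    marginal_corr_ : ndarray of shape (d,)
        IPC-weighted marginal correlations before decorrelation.
    ranks_ : ndarray of shape (d,)
        1 = largest \\|θ̂\\|, ties broken by column order.
    lambda_ : float
        Shrinkage intensity used.
    n_effective_ : float
        Sum of IPC weights (effective uncensored sample size).
    """

    def __init__(self, lambda_override=None, floor_nu=DEFAULT_FLOOR_NU):
        self.lambda_override = lambda_override
        self.floor_nu = floor_nu

    def fit(self, X, y):
        sample = as_sample(X, y, getattr(X, "columns", None))
        res = cars_scores(
            sample, lambda_override=self.lambda_override, floor_nu=self.floor_nu
        )
        self.result_ = res
        self.scores_ = res.scores
        self.marginal_corr_ = res.marginal_corr
        self.ranks_ = res.abs_rank
        self.lambda_ = res.lambda_used
        self.n_effective_ = res.n_effective
        self.n_features_in_ = sample.d
        self.feature_names_in_ = np.asarray(sample.covariate_names, dtype=object)
        return self
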