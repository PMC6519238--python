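"""Inverse-probability-of-censoring (IPC) weights.

Right-censoring biases ordinary moment estimators of the log survival time.
The fix is to reweight the uncensored observations by the inverse of the
estimated probability of remaining uncensored: the censoring survival
function ``G(t) = P(C > t)`` is estimated by applying the Kaplan–Meier
product-limit estimator with the *flipped* event indicator ``1 − Δ``
(censorings play the role of events), and observation ``i`` receives weight

    w_i = Δ_i / Ĝ(T̃_i⁻),

zero for censored rows. Ĝ is evaluated at the left limit so that an event
tied with a censoring time is not down-weighted by its own time point.

Because the logarithm is strictly monotone, the estimate computed on raw
times and evaluated at raw times is identical to the log-scale formulation;
the raw scale is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample import SurvivalSample

#: default positivity floor for Ĝ, mirroring the assumption G(·) > ν > 0
DEFAULT_FLOOR_NU = 1e-8


@dataclass(frozen=True)
class CensoringCurve:
    """Step-function Kaplan–Meier estimate of ``P(C > t)``.

    ``surv_values[k]`` is the value of Ĝ on ``[jump_times[k], jump_times[k+1])``;
    before the first jump Ĝ is 1. Evaluation is floored at ``floor_nu``.
    """

    jump_times: np.ndarray
    surv_values: np.ndarray
    floor_nu: float = DEFAULT_FLOOR_NU

    def __post_init__(self):
        jt = np.asarray(self.jump_times, dtype=float)
        sv = np.asarray(self.surv_values, dtype=float)
        if jt.shape != sv.shape:
            raise ValueError("jump_times and surv_values must have equal length")
        if jt.size and np.any(np.diff(jt) <= 0):
            raise ValueError("jump_times must be strictly increasing")
        if np.any(np.diff(sv) > 1e-15):
            raise ValueError("surv_values must be non-increasing")
        if self.floor_nu <= 0:
            raise ValueError("floor_nu must be positive")
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "surv_values", sv)

    def evaluate(self, t, left_limit: bool = False) -> np.ndarray:
        """Ĝ(t) (right-continuous) or Ĝ(t⁻) if ``left_limit``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.jump_times.size == 0:
            return np.ones_like(t)
        side = "left" if left_limit else "right"
        idx = np.searchsorted(self.jump_times, t, side=side)
        out = np.where(idx == 0, 1.0, self.surv_values[np.maximum(idx - 1, 0)])
        return np.maximum(out, self.floor_nu)


@dataclass(frozen=True)
class IPCWeightVector:
    """Per-observation IPC weights; zero exactly at censored indices."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        object.__setattr__(self, "weights", w)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.weights, dtype=dtype)

    @property
    def n_effective(self) -> float:
        return float(self.weights.sum())


def censoring_survival(
    sample: SurvivalSample, floor_nu: float = DEFAULT_FLOOR_NU
) -> CensoringCurve:
    """Kaplan–Meier estimate of the censoring survival function.

    The product-limit estimator is applied to the observed times with
    censorings (Δ = 0) treated as events. At tied times the survival events
    precede the censoring events, i.e. an event at ``t`` is still "at risk"
    for the censoring jump at ``t`` (standard reverse-KM convention).
    """
    if sample.n_events == 0:
        raise ValueError("no events: all observations are censored")
    times, status = sample.times, sample.status

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    distinct, first_idx = np.unique(t_sorted, return_index=True)
    # at-risk count at each distinct time u: #{T̃ >= u}
    n_at_risk = sample.n - first_idx
    # censoring "events" at u
    d_cens = np.zeros(distinct.size)
    np.add.at(d_cens, np.searchsorted(distinct, times), (status == 0).astype(float))
    factors = 1.0 - d_cens / n_at_risk
    surv = np.cumprod(factors)
    keep = d_cens > 0  # only censoring times move the curve
    return CensoringCurve(distinct[keep], surv[keep], floor_nu)


def ipc_weights(sample: SurvivalSample, curve: CensoringCurve) -> IPCWeightVector:
    """IPC weights ``w_i = Δ_i / max(Ĝ(T̃_i⁻), ν)``."""
    if curve.jump_times.size and curve.jump_times.max() > sample.times.max():
        raise ValueError("curve has jumps beyond the sample's time range")
    g_left = curve.evaluate(sample.times, left_limit=True)
    w = sample.status / g_left
    w[sample.status == 0] = 0.0
    return IPCWeightVector(w)


def compute_ipc_weights(
    sample: SurvivalSample, floor_nu: float = DEFAULT_FLOOR_NU, g_values=None
) -> IPCWeightVector:
    """Convenience: estimate Ĝ and return the weights in one call.

    ``g_values`` is an optional injection point for externally estimated
    per-sample censoring-survival evaluations Ĝ(T̃_i⁻ | x_i) (e.g. from a
    covariate-conditional censoring model); when given, the Kaplan–Meier
    step is skipped.
    """
    if g_values is not None:
        g = np.maximum(np.asarray(g_values, dtype=float), floor_nu)
        if g.shape[0] != sample.n:
            raise ValueError("g_values length must equal n")
        w = sample.status / g
        w[sample.status == 0] = 0.0
        return IPCWeightVector(w)
    return ipc_weights(sample, censoring_survival(sample, floor_nu))
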