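"""Container and validation for right-censored survival samples.

A sample holds observed times ``T̃ = min(T, C)``, event indicators
``Δ = I(T ≤ C)`` and an ``n × d`` covariate matrix. Log-times are computed
on demand, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SurvivalSample:
    """A right-censored survival dataset.

    Parameters
    ----------
    times : ndarray of shape (n,)
        Observed times, strictly positive (the log transform must exist).
    status : ndarray of shape (n,)
        Event indicators; 1 = event observed, 0 = right-censored.
    covariates : ndarray of shape (n, d)
        Covariate matrix, no missing values.
    covariate_names : tuple of str, optional
        Defaults to ``x1 … xd``.
    """

    times: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple = field(default=None)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        status = np.asarray(self.status)
        X = np.asarray(self.covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = times.shape[0]
        if n < 2:
            raise ValueError("need at least 2 observations")
        if status.shape[0] != n or X.shape[0] != n:
            raise ValueError(
                f"length mismatch: times {n}, status {status.shape[0]}, "
                f"covariates {X.shape[0]} rows"
            )
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("times must be finite and strictly positive")
        uniq = np.unique(status)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"status must be 0/1; found values {uniq}")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates contain missing or non-finite values")
        status = status.astype(np.int8)
        names = self.covariate_names
        if names is None:
            names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
        else:
            names = tuple(str(c) for c in names)
            if len(names) != X.shape[1]:
                raise ValueError("covariate_names length does not match d")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def d(self) -> int:
        return self.covariates.shape[1]

    @property
    def log_times(self) -> np.ndarray:
        return np.log(self.times)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


def make_survival_target(times, status) -> np.ndarray:
    """Pack times and event indicators into a structured target array.

    The layout (fields ``event`` then ``time``) follows the convention used
    by survival estimators in the scikit-learn ecosystem.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    y = np.empty(times.shape[0], dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = status.astype(bool)
    y["time"] = times
    return y


def unpack_survival_target(y):
    """Return ``(times, status)`` from a structured array or a 2-tuple."""
    if isinstance(y, np.ndarray) and y.dtype.names is not None:
        names = y.dtype.names
        ev = next((f for f in names if f.lower() in ("event", "status", "delta")), None)
        tm = next((f for f in names if f.lower() in ("time", "times")), None)
        if ev is None or tm is None:
            raise ValueError(
                f"structured target must have event/status and time fields; got {names}"
            )
        return np.asarray(y[tm], dtype=float), np.asarray(y[ev]).astype(np.int8)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return (np.asarray(y[0], dtype=float), np.asarray(y[1]).astype(np.int8))
    y = np.asarray(y)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(np.int8)
    raise ValueError(
        "survival target must be a structured array with (event, time) fields, "
        "a (times, status) pair, or an (n, 2) array of [time, status]"
    )


def as_sample(X, y, covariate_names=None) -> SurvivalSample:
    """Build a validated :class:`SurvivalSample` from estimator-style X, y."""
    times, status = unpack_survival_target(y)
    return SurvivalSample(times, status, np.asarray(X, dtype=float), covariate_names)
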