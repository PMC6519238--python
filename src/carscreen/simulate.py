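"""Synthetic survival studies with block-correlated covariates.

The generator reproduces a standard benchmark design for survival variable
screening: covariates are multivariate normal with a three-block
correlation structure (within-block correlations of magnitude 0.25, 0.5 and
0.75, randomly signed, zero between blocks, repaired to the nearest valid
correlation matrix); survival times follow an accelerated failure time
model, either lognormal (``log T = Xβ + ε``) or Weibull with log link
(``T ~ W(Φ = exp(Xβ), φ)``); and censoring combines a calibrated lognormal
censoring time with an administrative cutoff at the 90% quantile of T.

A designated fraction of covariates ("influential") carries coefficients
equidistant in [−0.9, 1]; the rest are null. Noise is calibrated so that a
target share of Var(log T) is explained (lognormal family) or a target
signal-to-noise ratio holds (Weibull family). Calibration constants are
estimated once on a large pilot draw and held fixed across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .sample import SurvivalSample

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "block_correlation_matrix",
    "nearest_correlation",
    "make_coefficients",
    "calibrate_lognormal_noise",
    "calibrate_weibull_shape",
    "calibrate_censoring",
    "simulate_dataset",
]

DEFAULT_BLOCK_RHOS = (0.25, 0.5, 0.75)
DEFAULT_PILOT_SIZE = 100_000


def _block_sizes(d: int) -> tuple:
    """Three near-equal block sizes: ceil(d/3), ceil(d/3), remainder."""
    b = -(-d // 3)
    if d - 2 * b < 1:
        b = d // 3
    return (b, b, d - 2 * b)


def nearest_correlation(A: np.ndarray, tol: float = 1e-7, max_iter: int = 200):
    """Nearest correlation matrix in the Frobenius norm (Higham's method).

    Alternating projections with Dykstra correction: project onto the PSD
    cone, restore the unit diagonal, repeat until the Frobenius change
    drops below ``tol``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("A must be symmetric")
    if not np.allclose(np.diag(A), 1.0, atol=1e-10):
        raise ValueError("A must have unit diagonal")

    Y = A.copy()
    dS = np.zeros_like(A)
    for it in range(max_iter):
        R = Y - dS
        evals, evecs = np.linalg.eigh(R)
        X = (evecs * np.maximum(evals, 0.0)) @ evecs.T
        X = (X + X.T) / 2
        dS = X - R
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        delta = np.linalg.norm(Y_new - Y, "fro")
        Y = Y_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"nearest_correlation did not converge in {max_iter} iterations "
            f"(last Frobenius change {delta:.3e})"
        )
    evals, evecs = np.linalg.eigh(Y)
    if evals.min() < 0:
        # final cleanup: clip the residual negative part left at the stopping
        # tolerance and rescale to a unit diagonal (PSD-preserving)
        Y = (evecs * np.maximum(evals, 0.0)) @ evecs.T
        dinv = 1.0 / np.sqrt(np.diag(Y))
        Y = Y * np.outer(dinv, dinv)
        Y = (Y + Y.T) / 2
        np.fill_diagonal(Y, 1.0)
        if np.linalg.eigvalsh(Y).min() < -1e-8:
            raise RuntimeError("nearest_correlation result not PSD after cleanup")
    return Y


def block_correlation_matrix(d: int, block_rhos=DEFAULT_BLOCK_RHOS, seed=0):
    """Three-block correlation matrix with half the within-block entries negative.

    Within block ``b`` every off-diagonal entry has magnitude
    ``|block_rhos[b]|`` and sign ``s_j · s_k``, where each covariate carries
    a sign ``s_j ∈ {±1}``: the first half of the block is positive, the
    second half negative. About 50% of the within-block correlations are
    therefore negative while the block stays an exact
    equicorrelation-with-signs matrix, ``|ρ| s sᵀ + (1 − |ρ|) I`` —
    positive definite by construction, so the nearest-correlation repair
    leaves the intended magnitudes intact. (Drawing every entry's sign
    independently instead yields a massively indefinite matrix whose
    nearest correlation matrix has entries shrunken far below ``ρ``,
    destroying the high-correlation design.) Leading block columns are
    mutually positively equicorrelated, so the influential set hosted there
    is equicorrelated, which is what defeats marginal screens: the shared
    group effect masks the influentials whose own coefficient opposes it.
    Entries between blocks are zero. The result is passed through
    :func:`nearest_correlation` as a guard. ``seed`` is kept for interface
    stability; the construction is deterministic.
    """
    if d < 6:
        raise ValueError("block structure needs d >= 6")
    del seed  # deterministic layout
    sizes = _block_sizes(d)
    A = np.zeros((d, d))
    start = 0
    for size, rho in zip(sizes, block_rhos):
        s = np.ones(size)
        s[-(size // 2) :] = -1.0
        block = abs(rho) * np.outer(s, s)
        A[start : start + size, start : start + size] = block
        start += size
    np.fill_diagonal(A, 1.0)
    return nearest_correlation(A)


def make_coefficients(k: int) -> np.ndarray:
    """``k`` coefficients equidistant in [−0.9, 1]; ``k = 1`` gives (1,)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    beta = np.linspace(-0.9, 1.0, k)
    if np.any(np.isclose(beta, 0.0)):
        warnings.warn(
            "equidistant coefficient grid contains an exact zero: one "
            "'influential' covariate has no effect (a property of the design)",
            UserWarning,
            stacklevel=2,
        )
    return beta


def calibrate_lognormal_noise(Sigma, beta_full, exp_var: float) -> float:
    """Noise variance achieving a target explained share of Var(log T).

    Closed form: with signal variance βᵀΣβ, the noise variance
    ``σ_ε² = βᵀΣβ (1 − expVar)/expVar`` gives
    ``Var(Xβ)/Var(log T) = expVar`` exactly.
    """
    if not 0.0 < exp_var < 1.0:
        raise ValueError("exp_var must lie in (0, 1)")
    signal = float(np.asarray(beta_full) @ np.asarray(Sigma) @ np.asarray(beta_full))
    if signal <= 0:
        raise ValueError("beta' Sigma beta is zero: no signal to calibrate against")
    return signal * (1.0 - exp_var) / exp_var


def calibrate_weibull_shape(
    Sigma, beta_full, snr: float = 0.5, pilot_size: int = DEFAULT_PILOT_SIZE, seed=0
) -> float:
    """Weibull shape φ achieving a target signal-to-noise ratio.

    SNR is operationalized as Var(E[log T | x]) / Var(log T − E[log T | x]).
    For ``T ~ W(Φ = exp(Xβ), φ)`` the residual log-time variance is
    ``π²/(6φ²)`` independent of x, so the target is solved by bisection on a
    pilot draw (the closed form φ = π √(snr / (6 βᵀΣβ)) is the test oracle).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    Sigma = np.asarray(Sigma, dtype=float)
    beta_full = np.asarray(beta_full, dtype=float)
    signal = float(beta_full @ Sigma @ beta_full)
    if signal <= 0:
        raise ValueError("beta' Sigma beta is zero: no signal to calibrate against")
    rng = np.random.default_rng(seed)
    # log of a shape-1 Weibull (= Exponential(1)) variate; scaling by 1/phi
    # gives the log-time residual for shape phi
    log_w = np.log(rng.exponential(size=pilot_size))

    def realized_snr(phi):
        resid = log_w / phi
        return signal / float(np.var(resid))

    lo, hi = 1e-3, 1e3
    if not realized_snr(lo) < snr < realized_snr(hi):
        raise RuntimeError(
            f"bisection bracket failure: snr({lo})={realized_snr(lo):.3g}, "
            f"snr({hi})={realized_snr(hi):.3g}, target {snr}"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if abs(realized_snr(mid) - snr) < 0.01 * snr:
            return float(mid)
        if realized_snr(mid) < snr:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one simulation scenario.

    Parameters mirror the benchmark grid: ``rel_var`` is the fraction of
    influential covariates, ``signal_block`` picks which correlation block
    hosts them (1 = |ρ| 0.25 … 3 = |ρ| 0.75), ``exp_var`` the explained
    log-scale variance (lognormal family), ``snr`` the signal-to-noise
    ratio (Weibull family), ``cens_rate`` the total target censoring
    fraction including the administrative cutoff at ``admin_quantile`` of T
    (``None`` disables the cutoff). ``cens_log_sd`` is the log-scale spread
    of the lognormal censoring time; ``None`` matches it to the pilot
    standard deviation of log T, keeping the censoring tail comparable to
    the outcome tail so that inverse-probability weights stay stable (used
    by the consistency studies; the benchmark scenarios keep the default 1).
    """

    n: int
    d: int
    rel_var: float = 0.1
    block_rhos: tuple = DEFAULT_BLOCK_RHOS
    signal_block: int = 1
    family: str = "lognormal"
    exp_var: float = 0.5
    snr: float = 0.5
    cens_rate: float = 0.25
    admin_quantile: float = 0.90
    cens_log_sd: float = 1.0
    seed: int = 0
    pilot_size: int = DEFAULT_PILOT_SIZE

    def __post_init__(self):
        if self.d < 6:
            raise ValueError("d must be >= 6")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.rel_var <= 1.0:
            raise ValueError("rel_var must lie in (0, 1]")
        if round(self.rel_var * self.d) < 1:
            raise ValueError("rel_var * d must be >= 1")
        if self.signal_block not in (1, 2, 3):
            raise ValueError("signal_block must be 1, 2 or 3")
        if self.family not in ("lognormal", "weibull"):
            raise ValueError("family must be 'lognormal' or 'weibull'")
        if not 0.0 < self.cens_rate < 1.0:
            raise ValueError("cens_rate must lie in (0, 1)")

    @property
    def n_influential(self) -> int:
        return int(round(self.rel_var * self.d))


@dataclass(frozen=True)
class SimulatedDataset:
    """One generated study plus its ground truth."""

    sample: SurvivalSample
    beta_true: np.ndarray
    influential_mask: np.ndarray
    realized_cens_rate: float
    correlation_matrix_used: np.ndarray
    design: SimulationDesign = field(default=None, repr=False)


class _ScenarioCalibration:
    """Pilot-draw constants shared by every replicate of one scenario."""

    def __init__(self, design: SimulationDesign):
        self.design = design
        d = design.d
        # seed for structure/calibration is distinct from replicate noise seeds
        self.corr = block_correlation_matrix(d, design.block_rhos, seed=design.seed)
        self.chol = _psd_factor(self.corr)
        sizes = _block_sizes(d)
        starts = np.concatenate([[0], np.cumsum(sizes)])
        b = design.signal_block - 1
        k = design.n_influential
        if starts[b] + k > d:
            raise ValueError(
                f"cannot place {k} influential covariates starting at block "
                f"{design.signal_block} (d={d})"
            )
        if k > sizes[b]:
            warnings.warn(
                f"{k} influential covariates exceed block {design.signal_block} "
                f"(size {sizes[b]}); spilling into subsequent columns",
                UserWarning,
                stacklevel=2,
            )
        idx = np.arange(starts[b], starts[b] + k)
        beta = np.zeros(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            beta[idx] = make_coefficients(k)
        self.beta = beta
        self.influential = np.zeros(d, dtype=bool)
        self.influential[idx] = True

        if design.family == "lognormal":
            self.sigma_eps2 = calibrate_lognormal_noise(self.corr, beta, design.exp_var)
            self.shape = None
        else:
            self.shape = calibrate_weibull_shape(
                self.corr, beta, design.snr, design.pilot_size, seed=design.seed
            )
            self.sigma_eps2 = None
        self.cens_log_mean, self.cens_log_sd, self.admin_cutoff = calibrate_censoring(
            design, self._draw_T, seed=design.seed, cens_log_sd=design.cens_log_sd
        )

    def _draw_T(self, rng: np.random.Generator, m: int) -> np.ndarray:
        """Draw m survival times from the scenario's AFT model."""
        Z = rng.standard_normal((m, self.design.d))
        xb = (Z @ self.chol.T) @ self.beta
        if self.design.family == "lognormal":
            eps = rng.normal(0.0, np.sqrt(self.sigma_eps2), m)
            return np.exp(xb + eps)
        w = rng.weibull(self.shape, m)
        return np.exp(xb) * w

    def draw(self, rng: np.random.Generator, n: int):
        Z = rng.standard_normal((n, self.design.d))
        X = Z @ self.chol.T
        xb = X @ self.beta
        if self.design.family == "lognormal":
            T = np.exp(xb + rng.normal(0.0, np.sqrt(self.sigma_eps2), n))
        else:
            T = np.exp(xb) * rng.weibull(self.shape, n)
        C = np.exp(rng.normal(self.cens_log_mean, self.cens_log_sd, n))
        C = np.minimum(C, self.admin_cutoff)
        observed = np.minimum(T, C)
        status = (T <= C).astype(np.int8)
        return X, observed, status


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ ≈ corr, tolerant of the −1e−8 eigenvalue slack."""
    evals, evecs = np.linalg.eigh(corr)
    return evecs * np.sqrt(np.maximum(evals, 0.0))


def calibrate_censoring(
    design: SimulationDesign, survival_generator, seed=0, cens_log_sd: float = 1.0
):
    """Calibrate the lognormal censoring time to a total censoring target.

    The administrative cutoff is the ``admin_quantile`` (default 90%)
    empirical quantile of T on a pilot draw and stays fixed. The lognormal
    log-mean (log-sd fixed at 1) is then found by bisection so that the
    total censoring fraction — random plus administrative — matches
    ``cens_rate`` within 0.01 on the pilot. ``admin_quantile=None`` disables
    the cutoff (purely random censoring, as assumed by the consistency
    theory: the censoring survival function stays positive everywhere).

    ``survival_generator(rng, m)`` must return m independent draws of T.
    Returns ``(cens_log_mean, cens_log_sd, admin_cutoff)``.
    """
    rng = np.random.default_rng(seed)
    T = survival_generator(rng, design.pilot_size)
    if cens_log_sd is None:
        cens_log_sd = float(np.std(np.log(T)))
    if design.admin_quantile is None:
        cutoff = np.inf
    else:
        cutoff = float(np.quantile(T, design.admin_quantile))
    admin_floor = float(np.mean(T > cutoff))
    if design.cens_rate < admin_floor - 0.005:
        raise ValueError(
            f"administrative censoring alone ({admin_floor:.3f}) exceeds the "
            f"target rate {design.cens_rate}"
        )
    # one shared censoring draw keeps the bisection objective monotone
    z = rng.standard_normal(design.pilot_size)

    def cens_frac(log_mean):
        C = np.minimum(np.exp(log_mean + cens_log_sd * z), cutoff)
        return float(np.mean(T > C))

    log_t = np.log(T)
    lo = float(np.min(log_t)) - 6 * cens_log_sd  # censor nearly everything
    hi = float(min(np.log(cutoff), np.max(log_t))) + 6 * cens_log_sd  # ~no censoring
    if not cens_frac(hi) <= design.cens_rate <= cens_frac(lo):
        raise ValueError(
            f"target censoring rate {design.cens_rate} unreachable: bisection "
            f"range gives [{cens_frac(hi):.3f}, {cens_frac(lo):.3f}]"
        )
    for _ in range(100):
        mid = (lo + hi) / 2
        frac = cens_frac(mid)
        if abs(frac - design.cens_rate) < 0.01:
            return float(mid), float(cens_log_sd), cutoff
        if frac > design.cens_rate:
            lo = mid
        else:
            hi = mid
    return float((lo + hi) / 2), float(cens_log_sd), cutoff


def simulate_dataset(design: SimulationDesign, calibration=None) -> SimulatedDataset:
    """Generate one study from a design, fully reproducible from its seed.

    ``calibration`` may carry a precomputed :class:`_ScenarioCalibration`
    to share pilot constants across replicates of the same scenario.
    """
    cal = calibration if calibration is not None else _ScenarioCalibration(design)
    rng = np.random.default_rng(design.seed)
    X, observed, status = cal.draw(rng, design.n)
    if status.sum() == 0:  # pathological tiny-n draw; resample once
        X, observed, status = cal.draw(rng, design.n)
    realized = float(np.mean(status == 0))
    if design.n >= 500 and abs(realized - design.cens_rate) > 0.05:
        warnings.warn(
            f"realized censoring rate {realized:.3f} is more than 0.05 from "
            f"the target {design.cens_rate}",
            UserWarning,
            stacklevel=2,
        )
    sample = SurvivalSample(observed, status, X)
    return SimulatedDataset(
        sample=sample,
        beta_true=cal.beta.copy(),
        influential_mask=cal.influential.copy(),
        realized_cens_rate=realized,
        correlation_matrix_used=cal.corr,
        design=design,
    )


def scenario_calibration(design: SimulationDesign) -> _ScenarioCalibration:
    """Precompute the pilot constants of a scenario for reuse across replicates."""
    return _ScenarioCalibration(design)


def replicate_design(design: SimulationDesign, replicate_seed: int) -> SimulationDesign:
    """A copy of ``design`` with a different noise seed (same scenario)."""
    return replace(design, seed=int(replicate_seed))
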