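"""Shrinkage estimation of the covariate correlation matrix and whitening.

When the number of covariates d exceeds the sample size n, the sample
correlation matrix R_X is singular and its inverse square root — the
whitening transform that decorrelates the covariates — does not exist. The
remedy is linear shrinkage towards the identity,

    R_shrink = λ I_d + (1 − λ) R_X,

with the data-driven intensity

    λ = Σ_{j≠k} Var̂(r_jk) / Σ_{j≠k} r_jk²,

clamped to [0, 1]. Var̂(r_jk) is the unbiased estimator
``n/(n−1)³ · Σ_i (w_ijk − w̄_jk)²`` with ``w_ijk`` the product of the i-th
standardized entries of columns j and k.

``R_shrink^{−1/2}`` is never formed as a d × d matrix. With (U, μ) the
non-null eigenpairs of R_X (from an SVD of the standardized data),

    R_shrink^{−1/2} = λ^{−1/2} I + U [ (λ + (1−λ) μ)^{−1/2} − λ^{−1/2} ] Uᵀ,

so applying it to a vector costs O(d·m) with m ≤ min(n−1, d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: below this dimension a dense eigendecomposition is used instead of the SVD
DENSE_EIG_MAX_D = 64

_RANK_TOL = 1e-12


def standardize_columns(X: np.ndarray):
    """Center and scale columns to unit sample variance (n−1 divisor).

    Returns ``(Xs, means, sds)``. Constant columns make correlations
    undefined and raise, naming the offenders.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an n x d matrix with n >= 2")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(
            f"constant covariate column(s) at index {bad.tolist()}: "
            "correlations are undefined"
        )
    return (X - means) / sds, means, sds


def shrinkage_intensity(Xs: np.ndarray) -> float:
    """Data-driven shrinkage intensity λ ∈ [0, 1] from standardized data.

    Computed without forming any d × d matrix: both the sum of squared
    off-diagonal correlations and the summed pairwise variances reduce to
    row-norm and n × n Gram-matrix expressions.
    """
    Xs = np.asarray(Xs, dtype=float)
    n, d = Xs.shape
    if d < 2:
        return 1.0
    if n < 3:
        raise ValueError("shrinkage intensity needs n >= 3")

    # tr(R^2) = ||Xs^T Xs||_F^2 / (n-1)^2 = ||Xs Xs^T||_F^2 / (n-1)^2 ;
    # form whichever cross-product is smaller
    G = Xs.T @ Xs if d <= n else Xs @ Xs.T
    sum_r2_all = float((G * G).sum()) / (n - 1) ** 2
    diag_r2 = d  # r_jj = 1
    denom = sum_r2_all - diag_r2

    # Σ_{jk} Σ_i (w_ijk - w̄_jk)^2 = Σ_{jk} [Σ_i w_ijk^2 - n w̄_jk^2]
    # Σ_i Σ_{jk} w_ijk^2 = Σ_i (Σ_j Xs_ij^2)^2 ; w̄_jk = r_jk (n-1)/n
    sq_rows = (Xs * Xs).sum(axis=1)
    sum_w2_all = float((sq_rows * sq_rows).sum())
    sum_wbar2_all = ((n - 1) / n) ** 2 * sum_r2_all
    # diagonal (j = k) contribution, removed explicitly
    w_diag = Xs * Xs  # w_ijj
    diag_dev = ((w_diag - (n - 1) / n) ** 2).sum()
    ss_offdiag = sum_w2_all - n * sum_wbar2_all - float(diag_dev)
    numer = n / (n - 1) ** 3 * ss_offdiag

    if denom <= 0:
        return 1.0
    return float(np.clip(numer / denom, 0.0, 1.0))


@dataclass(frozen=True)
class ShrinkageOperator:
    """Lazily evaluated ``R_shrink^{−1/2}`` (and powers) for d ≫ n.

    Stores only the non-null eigenpairs of R_X: orthonormal eigenvectors
    ``left_vectors`` (d × m) and ``eigenvalues`` (length m). Eigenvalues of
    R_X outside this column space are 0, where R_shrink reduces to λ.
    """

    lambda_hat: float
    left_vectors: np.ndarray
    eigenvalues: np.ndarray
    d: int

    def __post_init__(self):
        U = np.asarray(self.left_vectors, dtype=float)
        mu = np.asarray(self.eigenvalues, dtype=float)
        if U.shape[1] != mu.shape[0]:
            raise ValueError("eigenpair count mismatch")
        if not 0.0 <= self.lambda_hat <= 1.0:
            raise ValueError("lambda_hat must lie in [0, 1]")
        if np.any(mu < -1e-10):
            raise ValueError("negative eigenvalue in R_X factorization")
        object.__setattr__(self, "left_vectors", U)
        object.__setattr__(self, "eigenvalues", np.maximum(mu, 0.0))

    @property
    def rank(self) -> int:
        return self.eigenvalues.shape[0]

    def _apply_power(self, V: np.ndarray, power: float) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        squeeze = V.ndim == 1
        if squeeze:
            V = V[:, None]
        if V.shape[0] != self.d:
            raise ValueError(f"operand has {V.shape[0]} rows, expected d={self.d}")
        lam = self.lambda_hat
        shrunk_eig = lam + (1.0 - lam) * self.eigenvalues
        if lam == 0.0 and (self.rank < self.d or np.any(shrunk_eig < _RANK_TOL)):
            raise ValueError(
                "R_shrink singular; lambda must be > 0 when d exceeds the rank of R_X"
            )
        base = lam**power if lam > 0 else 0.0
        coeff = shrunk_eig**power - base
        out = base * V + self.left_vectors @ (coeff[:, None] * (self.left_vectors.T @ V))
        return out[:, 0] if squeeze else out

    def apply_inv_sqrt(self, V: np.ndarray) -> np.ndarray:
        """``R_shrink^{−1/2} V`` in O(d·m·k) without a dense matrix."""
        return self._apply_power(V, -0.5)

    def apply(self, V: np.ndarray) -> np.ndarray:
        """``R_shrink V`` (mainly for verification)."""
        return self._apply_power(V, 1.0)

    def apply_inv(self, V: np.ndarray) -> np.ndarray:
        """``R_shrink^{−1} V``."""
        return self._apply_power(V, -1.0)

    def dense(self) -> np.ndarray:
        """Materialize R_shrink (small-d diagnostics only)."""
        U, mu = self.left_vectors, self.eigenvalues
        lam = self.lambda_hat
        return lam * np.eye(self.d) + (1 - lam) * (U * mu) @ U.T


def build_shrink_op(Xs: np.ndarray, lambda_hat: float) -> ShrinkageOperator:
    """Factor R_X from standardized data and wrap it with shrinkage λ.

    For d ≤ 64 a dense symmetric eigendecomposition of R_X is used; above
    that, the economy SVD of ``Xs/√(n−1)`` (cost O(n²d), no d × d matrix).
    Both paths store the same eigenpairs up to null-space truncation.
    """
    Xs = np.asarray(Xs, dtype=float)
    n, d = Xs.shape
    if not 0.0 <= lambda_hat <= 1.0:
        raise ValueError("lambda_hat must lie in [0, 1]")
    A = Xs / np.sqrt(n - 1)
    if d <= DENSE_EIG_MAX_D:
        mu, U = np.linalg.eigh(A.T @ A)
        keep = mu > _RANK_TOL * max(mu.max(initial=0.0), 1.0)
        mu, U = mu[keep], U[:, keep]
    else:
        _, s, Vt = np.linalg.svd(A, full_matrices=False)
        mu = s**2
        keep = mu > _RANK_TOL * max(mu.max(initial=0.0), 1.0)
        mu, U = mu[keep], Vt[keep].T
    if lambda_hat == 0.0 and mu.shape[0] < d:
        raise ValueError(
            "R_shrink singular; lambda must be > 0 when d exceeds the rank of R_X"
        )
    return ShrinkageOperator(float(lambda_hat), U, mu, d)


def apply_inv_sqrt(op: ShrinkageOperator, V: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`ShrinkageOperator.apply_inv_sqrt`."""
    return op.apply_inv_sqrt(V)
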