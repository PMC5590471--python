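"""Least-squares flux estimation: OLS/GLS fits, covariances and ANOVA.

The mole balance ``S_I v_I = -S_E v_E`` is cast as the linear model
``y = X beta + e`` with ``y = -S_E v_E``, ``X = S_I`` and ``beta = v_I``.
OLS gives ``beta = (X'X)^-1 X'y`` with ``Cov = sigma^2 (X'X)^-1``; when the
measurement-error covariance ``Cov(e)`` is known, GLS whitens the problem
with a Cholesky factor ``Cov(e) = LL'`` and reduces to OLS on
``L^-1 y = L^-1 X beta``, giving ``Cov = (X' Cov(e)^-1 X)^-1``.

Numerically both fits go through an orthogonal (QR) decomposition rather
than the normal equations; results agree with the explicit formulas to
tolerance (asserted in the test suite).

The regression has no intercept -- y is a balance residual with no natural
mean term -- so the significance-of-regression ANOVA uses the uncentered
decomposition SST = y'y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .stoichio import EstimabilityError, PartitionedModel, check_estimability

#: zero-variance rows of Cov(e) receive this fraction of the smallest
#: nonzero propagated variance (1.0 if none), keeping Cov(e) invertible while
#: treating unmeasured balances as near-hard constraints.
DEFAULT_VARIANCE_FLOOR = 1e-6


@dataclass
class RegressionProblem:
    """The flux-estimation linear model ``y = X beta + e``.

    ``cov_e`` is the N x N measurement-error covariance; ``None`` selects the
    plain OLS model.  Construction enforces N >= K and full column rank of X.
    """

    y: np.ndarray
    X: np.ndarray
    cov_e: np.ndarray | None = None
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        N, K = self.X.shape
        if self.y.shape[0] != N:
            raise ValueError(f"y has length {self.y.shape[0]}, X has {N} rows")
        if N < K:
            raise EstimabilityError(f"underdetermined: N={N} < K={K}")
        report = check_estimability(self.X)
        if not report.is_estimable:
            raise EstimabilityError(
                f"X rank {report.numerical_rank} < {K} columns", report)
        if self.cov_e is not None:
            self.cov_e = np.asarray(self.cov_e, dtype=float)
            if self.cov_e.shape != (N, N):
                raise ValueError("cov_e shape mismatch")
            if not np.allclose(self.cov_e, self.cov_e.T, atol=1e-12):
                raise ValueError("cov_e not symmetric")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]


@dataclass
class FluxEstimate:
    """A fitted flux vector with its covariance and residual diagnostics.

    ``sse`` is the minimized error function: the plain residual sum of
    squares for OLS, the covariance-weighted (whitened) sum for GLS.
    ``residuals`` are always on the raw scale, ``e = y - X beta``.
    """

    beta_hat: np.ndarray
    cov_beta: np.ndarray
    residuals: np.ndarray
    sse: float
    dof_error: int
    method: str
    sigma2: float
    col_labels: list[str] | None = None

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


@dataclass
class AnovaResult:
    """Uncentered significance-of-regression ANOVA (F test of beta = 0)."""

    f_statistic: float
    df_model: int
    df_error: int
    p_value: float
    exact_fit: bool = False


def build_regression(pm: PartitionedModel,
                     variance_floor: float = DEFAULT_VARIANCE_FLOOR
                     ) -> RegressionProblem:
    """Assemble ``y = -S_E v_E`` and the propagated error covariance.

    The covariance of the balance residuals is ``S_E diag(sd_E^2) S_E'``.
    Rows with (numerically) zero propagated variance -- unmeasured balances,
    or zero sd -- receive a small variance floor so the matrix is invertible;
    variances below 1e-12 of the largest count as zero, which keeps the
    whitening transform numerically sane when a measured flux happens to be
    almost exactly zero.  If the floored matrix is still not positive
    definite (perfectly correlated rows), the floor is added to the whole
    diagonal.
    """
    y = -pm.S_E @ pm.v_E
    cov = pm.S_E @ np.diag(pm.sd_E ** 2) @ pm.S_E.T
    d = np.diag(cov).copy()
    zero = d <= 1e-12 * (d.max() if d.size else 0.0)
    nonzero = d[~zero]
    if nonzero.size == 0:
        warnings.warn("all measurement sds are zero; Cov(e) set to the "
                      "variance floor on the diagonal")
    base = nonzero.min() if nonzero.size else 1.0
    floor = variance_floor * base
    cov = cov + np.diag(np.where(zero, floor - d, 0.0))
    try:
        sla.cholesky(cov, lower=True)
    except sla.LinAlgError:
        cov = cov + floor * np.eye(cov.shape[0])
    return RegressionProblem(
        y=y, X=pm.S_I, cov_e=cov,
        row_labels=list(pm.metabolite_ids),
        col_labels=list(pm.internal_ids),
    )


def _qr_solve(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares via thin QR; returns (beta, (X'X)^-1)."""
    Q, R = np.linalg.qr(X)
    beta = sla.solve_triangular(R, Q.T @ y)
    Rinv = sla.solve_triangular(R, np.eye(R.shape[0]))
    return beta, Rinv @ Rinv.T


def ols_fit(problem: RegressionProblem) -> FluxEstimate:
    """Ordinary least squares: ``beta = (X'X)^-1 X'y``.

    The estimate covariance is ``sigma^2 (X'X)^-1`` with the unbiased noise
    variance estimate ``sigma^2 = SSE / (N - K)`` (``sigma^2 = 0`` reported
    for saturated fits with N = K).
    """
    beta, XtX_inv = _qr_solve(problem.X, problem.y)
    resid = problem.y - problem.X @ beta
    sse = float(resid @ resid)
    dof = problem.N - problem.K
    sigma2 = sse / dof if dof > 0 else 0.0
    return FluxEstimate(
        beta_hat=beta, cov_beta=sigma2 * XtX_inv, residuals=resid,
        sse=sse, dof_error=dof, method="ols", sigma2=sigma2,
        col_labels=problem.col_labels,
    )


def whiten_problem(problem: RegressionProblem) -> RegressionProblem:
    """Return the OLS-equivalent whitened problem ``L^-1 y = L^-1 X beta``.

    ``L`` is the lower Cholesky factor of ``cov_e``; raises if ``cov_e`` is
    absent or not positive definite.
    """
    if problem.cov_e is None:
        raise ValueError("problem has no cov_e to whiten with")
    try:
        L = sla.cholesky(problem.cov_e, lower=True)
    except sla.LinAlgError as exc:
        raise EstimabilityError(
            "cov_e is not positive definite; cannot whiten") from exc
    yw = sla.solve_triangular(L, problem.y, lower=True)
    Xw = sla.solve_triangular(L, problem.X, lower=True)
    return RegressionProblem(y=yw, X=Xw, cov_e=None,
                             row_labels=problem.row_labels,
                             col_labels=problem.col_labels)


def whiten_matrix(problem: RegressionProblem, M: np.ndarray) -> np.ndarray:
    """Apply the same whitening transform ``L^-1 M`` to an auxiliary matrix."""
    L = sla.cholesky(problem.cov_e, lower=True)
    return sla.solve_triangular(L, np.asarray(M, dtype=float), lower=True)


def gls_fit(problem: RegressionProblem) -> FluxEstimate:
    """Generalized least squares via whitening.

    Equivalent to minimizing ``(y - X b)' Cov(e)^-1 (y - X b)``; the estimate
    covariance is ``(X' Cov(e)^-1 X)^-1`` (no noise-variance scaling, since
    Cov(e) is taken as known).
    """
    wp = whiten_problem(problem)
    beta, XtWX_inv = _qr_solve(wp.X, wp.y)
    resid_w = wp.y - wp.X @ beta
    sse = float(resid_w @ resid_w)
    dof = problem.N - problem.K
    return FluxEstimate(
        beta_hat=beta, cov_beta=XtWX_inv,
        residuals=problem.y - problem.X @ beta,
        sse=sse, dof_error=dof, method="gls",
        sigma2=sse / dof if dof > 0 else 0.0,
        col_labels=problem.col_labels,
    )


def fit(problem: RegressionProblem, method: str = "auto") -> FluxEstimate:
    """Dispatch to :func:`gls_fit` when a covariance is present, else OLS."""
    if method == "auto":
        method = "gls" if problem.cov_e is not None else "ols"
    if method == "gls":
        return gls_fit(problem)
    if method == "ols":
        return ols_fit(problem)
    raise ValueError(f"unknown method {method!r}")


def regression_anova(est: FluxEstimate, problem: RegressionProblem,
                     exact_fit_tol: float = 1e-12) -> AnovaResult:
    """Overall F test of the regression, uncentered (no-intercept model).

    F = (SSR / K) / (SSE / (N - K)) with SST = y'y on the whitened scale for
    GLS fits.  An (essentially) exact fit is reported with p = 0 and the
    ``exact_fit`` flag set.
    """
    if est.method == "gls":
        wp = whiten_problem(problem)
        y = wp.y
    else:
        y = problem.y
    N, K = problem.N, problem.K
    sst = float(y @ y)
    sse = est.sse
    ssr = max(sst - sse, 0.0)
    df_error = N - K
    if sse <= exact_fit_tol * max(sst, 1.0):
        return AnovaResult(np.inf, K, df_error, 0.0, exact_fit=True)
    f_stat = (ssr / K) / (sse / df_error)
    p = float(stats.f.sf(f_stat, K, df_error))
    return AnovaResult(float(f_stat), K, df_error, p)
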