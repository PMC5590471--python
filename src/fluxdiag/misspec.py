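"""Misspecification diagnostics for overdetermined MFA.

Omitting true reactions from the stoichiometric model biases the flux
estimate: if the true balance is ``S_E v_E + S_I v_I + S_O v_O = 0`` but the
fit uses only ``S_I``, the OLS estimate has expectation shifted by

    bias = (S_I' S_I)^-1 S_I' S_O v_O

which scales with the stoichiometric correlation between retained and
omitted reactions and with the omitted flux magnitudes -- a small-flux
reaction can still produce a large bias if its stoichiometry is strongly
correlated with the retained columns.

Three specification tests are provided:

* ``reset_test`` -- Ramsey's RESET: augment the design with powers of the
  fitted values; needs no knowledge of the candidate reactions.
* ``f_test`` -- nested extra-sum-of-squares F test of candidate reaction
  columns Z (H0: their fluxes are zero).
* ``lm_test`` -- Lagrange-multiplier score test of correlation between the
  residuals and Z residualized against [1 X], with a
  heteroscedasticity-consistent weighting (Omega = diag(e_i^2)).

All tests operate on the plain OLS problem; when the problem carries a
measurement-error covariance they are applied to the whitened
(OLS-equivalent) problem, with Z whitened by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fluxreg import RegressionProblem, ols_fit, whiten_matrix, whiten_problem
from .stoichio import (EstimabilityError, MetabolicModel, ModelValidationError,
                       check_estimability)

DEFAULT_ALPHA = 0.05

#: base-model fits with SSE below this fraction of y'y are treated as exact:
#: the statistics are then defined as 0 (no detectable misspecification)
#: instead of the indeterminate 0/0 ratio.
EXACT_FIT_TOL = 1e-12


@dataclass
class OmittedBlock:
    """Stoichiometry ``S_O`` and fluxes ``v_O`` of reactions absent from a model."""

    S_O: np.ndarray
    v_O: np.ndarray
    reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.S_O = np.atleast_2d(np.asarray(self.S_O, dtype=float))
        self.v_O = np.asarray(self.v_O, dtype=float).ravel()
        if self.S_O.shape[1] != self.v_O.shape[0]:
            raise ValueError("S_O column count does not match v_O length")


@dataclass
class CandidateBlock:
    """Design matrix Z of candidate missing reactions (model row order)."""

    Z: np.ndarray
    reaction_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not self.reaction_ids:
            self.reaction_ids = [f"Z{j + 1}" for j in range(self.Z.shape[1])]
        if len(self.reaction_ids) != self.Z.shape[1]:
            raise ValueError("candidate id count does not match Z columns")

    @property
    def n_candidates(self) -> int:
        return self.Z.shape[1]


@dataclass
class BiasResult:
    """Specification bias of the internal-flux estimate from omitted reactions."""

    bias: np.ndarray
    relative_bias: np.ndarray | None  # percent; NaN where reference flux is 0
    summary: dict[str, float]
    flux_ids: list[str] | None = None


@dataclass
class TestResult:
    """Outcome of one misspecification test at significance level alpha.

    ``reject`` follows the critical-value comparison exactly as each
    statistic's reference prescribes (strict ``>`` for RESET, ``>=`` for the
    F and LM tests); with continuous statistics this agrees with
    ``p_value <= alpha`` almost surely, and ties have probability zero.
    """

    test_name: str
    statistic: float
    df: tuple[int, ...]
    critical_value: float
    p_value: float
    alpha: float
    reject: bool
    candidate_ids: list[str] | None = None


def load_candidates(path: str | Path, model: MetabolicModel,
                    allow_missing_rows: bool = False) -> CandidateBlock:
    """Read candidate reactions from a TSV table aligned to a model's metabolites.

    By default every model metabolite must appear as a row; with
    ``allow_missing_rows`` absent rows are treated as zero coefficients.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    missing = [m for m in model.metabolite_ids if m not in df.index]
    if missing and not allow_missing_rows:
        raise ModelValidationError(
            f"candidate table missing metabolite rows: {missing}")
    extra = [m for m in df.index if m not in model.metabolite_ids]
    if extra:
        raise ModelValidationError(
            f"candidate table has unknown metabolites: {extra}")
    aligned = df.reindex(model.metabolite_ids).fillna(0.0)
    return CandidateBlock(Z=aligned.to_numpy(dtype=float),
                         reaction_ids=[str(c) for c in df.columns])


def specification_bias(S_I: np.ndarray, S_O: np.ndarray, v_O: np.ndarray,
                       cov_e: np.ndarray | None = None,
                       reference: np.ndarray | None = None,
                       flux_ids: list[str] | None = None) -> BiasResult:
    """Closed-form bias of the flux estimate caused by omitted reactions.

    OLS: ``(S_I'S_I)^-1 S_I'S_O v_O``; with ``cov_e`` the GLS analogue
    ``(S_I' W S_I)^-1 S_I' W S_O v_O`` with ``W = cov_e^-1``, computed by
    whitening.  ``relative_bias`` is the bias in percent of a caller-supplied
    reference flux vector (typically the full-model estimate); entries with a
    zero reference are NaN and excluded from the summary.
    """
    S_I = np.asarray(S_I, dtype=float)
    S_O = np.atleast_2d(np.asarray(S_O, dtype=float))
    v_O = np.asarray(v_O, dtype=float).ravel()
    if S_O.shape[0] != S_I.shape[0]:
        raise ValueError("S_O and S_I row dimensions differ")
    if S_O.shape[1] != v_O.shape[0]:
        raise ValueError("S_O column count does not match v_O")
    target = S_O @ v_O
    if cov_e is not None:
        # whiten both sides: argmin ||L^-1 S_I b - L^-1 target||
        dummy = RegressionProblem(y=target, X=S_I, cov_e=np.asarray(cov_e, float))
        wp = whiten_problem(dummy)
        S_I_w, target_w = wp.X, wp.y
    else:
        S_I_w, target_w = S_I, target
    report = check_estimability(S_I_w)
    if not report.is_estimable:
        raise EstimabilityError("S_I is rank deficient", report)
    bias, *_ = np.linalg.lstsq(S_I_w, target_w, rcond=None)

    relative = None
    values = np.abs(bias)
    if reference is not None:
        reference = np.asarray(reference, dtype=float).ravel()
        if reference.shape != bias.shape:
            raise ValueError("reference flux vector has wrong length")
        with np.errstate(divide="ignore", invalid="ignore"):
            relative = 100.0 * bias / reference
        # a reference flux that is numerically zero (including structural
        # zeros of order machine precision) makes the percent undefined
        zero_ref = np.abs(reference) <= 1e-9 * np.max(np.abs(reference), initial=0.0)
        relative[zero_ref] = np.nan
        values = np.abs(relative[~np.isnan(relative)])
    if values.size:
        summary = {"min": float(values.min()),
                   "median": float(np.median(values)),
                   "mean": float(values.mean()),
                   "max": float(values.max())}
    else:
        summary = {"min": np.nan, "median": np.nan, "mean": np.nan, "max": np.nan}
    return BiasResult(bias=bias, relative_bias=relative, summary=summary,
                      flux_ids=flux_ids)


def _as_ols(problem: RegressionProblem,
            Z: np.ndarray | None = None
            ) -> tuple[RegressionProblem, np.ndarray | None]:
    """Whiten a GLS problem (and Z) so the tests can run on an OLS problem."""
    if problem.cov_e is None:
        return problem, Z
    wp = whiten_problem(problem)
    Zw = whiten_matrix(problem, Z) if Z is not None else None
    return wp, Zw


def reset_test(problem: RegressionProblem, order_p: int = 1,
               alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Ramsey's RESET test of order p.

    Fits the base model, augments the design with elementwise powers
    ``yhat^2 ... yhat^(p+1)`` of the fitted values, and compares the two
    residual sums of squares:

        S = ((SSE0 - SSE1) / p) / (SSE1 / (N - K - p))

    rejecting when S exceeds the F(p, N-K-p) upper-alpha quantile.  Fitted
    values are scaled by max|yhat| before exponentiation (the statistic is
    scale invariant in exact arithmetic; the scaling only prevents overflow
    for large flux magnitudes).
    """
    if order_p < 1:
        raise ValueError("order_p must be >= 1")
    problem, _ = _as_ols(problem)
    N, K = problem.N, problem.K
    df2 = N - K - order_p
    if df2 <= 0:
        raise ValueError(f"not enough error degrees of freedom: N-K-p = {df2}")
    base = ols_fit(problem)
    if base.sse <= EXACT_FIT_TOL * max(float(problem.y @ problem.y), EXACT_FIT_TOL):
        crit = float(stats.f.ppf(1 - alpha, order_p, df2))
        return TestResult("RESET", 0.0, (order_p, df2), crit, 1.0, alpha, False)
    yhat = problem.X @ base.beta_hat
    scale = np.max(np.abs(yhat))
    if scale == 0:
        raise ValueError("fitted values are identically zero; RESET powers degenerate")
    powers = np.column_stack([(yhat / scale) ** (j + 1)
                              for j in range(1, order_p + 1)])
    augmented = np.column_stack([problem.X, powers])
    if not check_estimability(augmented).is_estimable:
        raise EstimabilityError(
            "fitted-value power columns are collinear with the design; "
            "use a lower RESET order p")
    coef, *_ = np.linalg.lstsq(augmented, problem.y, rcond=None)
    resid1 = problem.y - augmented @ coef
    sse1 = float(resid1 @ resid1)
    drop = max(base.sse - sse1, 0.0)
    if sse1 == 0.0:
        statistic = np.inf
    else:
        statistic = (drop / order_p) / (sse1 / df2)
    crit = float(stats.f.ppf(1 - alpha, order_p, df2))
    p_value = float(stats.f.sf(statistic, order_p, df2))
    return TestResult("RESET", float(statistic), (order_p, df2), crit,
                      p_value, alpha, bool(statistic > crit))


def f_test(problem: RegressionProblem, cand: CandidateBlock,
           alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Nested F test of candidate reaction columns Z (H0: alpha = 0).

        S = ((SSE0 - SSE1) / o) / (SSE1 / (N - K - o))

    where SSE1 comes from the augmented fit on ``[X Z]``, which must have
    full column rank; rejection at the F(o, N-K-o) upper-alpha quantile.
    """
    problem, Z = _as_ols(problem, cand.Z)
    N, K = problem.N, problem.K
    o = cand.n_candidates
    if Z.shape[0] != N:
        raise ValueError("Z row dimension does not match the problem")
    df2 = N - K - o
    if df2 <= 0:
        raise ValueError(f"not enough error degrees of freedom: N-K-o = {df2}")
    augmented = np.column_stack([problem.X, Z])
    if not check_estimability(augmented).is_estimable:
        dependent = _dependent_columns(problem.X, Z, cand.reaction_ids)
        raise EstimabilityError(
            f"[X Z] is rank deficient; dependent candidate columns: {dependent}")
    base = ols_fit(problem)
    crit = float(stats.f.ppf(1 - alpha, o, df2))
    if base.sse <= EXACT_FIT_TOL * max(float(problem.y @ problem.y), EXACT_FIT_TOL):
        return TestResult("F", 0.0, (o, df2), crit, 1.0, alpha, False,
                          list(cand.reaction_ids))
    coef, *_ = np.linalg.lstsq(augmented, problem.y, rcond=None)
    resid1 = problem.y - augmented @ coef
    sse1 = float(resid1 @ resid1)
    drop = max(base.sse - sse1, 0.0)
    statistic = np.inf if sse1 == 0.0 else (drop / o) / (sse1 / df2)
    p_value = float(stats.f.sf(statistic, o, df2))
    return TestResult("F", float(statistic), (o, df2), crit, p_value, alpha,
                      bool(statistic >= crit), list(cand.reaction_ids))


def lm_test(problem: RegressionProblem, cand: CandidateBlock,
            alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Heteroscedasticity-consistent Lagrange-multiplier test.

    Residualizes Z against the intercept-augmented design ``X_ = [1 X]``,

        Zc = Z - X_ (X_'X_)^-1 X_' Z,

    weights with ``Omega = diag(e_i^2)`` from the base OLS residuals, and
    computes

        S = e' Zc ( (N-K)/(N-K-o) Zc' Omega Zc )^-1 Zc' e,

    rejecting when S meets the chi-square(o) upper-alpha quantile.  K counts
    the columns of X only; the intercept column enters Zc exactly as written.
    """
    problem, Z = _as_ols(problem, cand.Z)
    N, K = problem.N, problem.K
    o = cand.n_candidates
    if Z.shape[0] != N:
        raise ValueError("Z row dimension does not match the problem")
    if N - K - o <= 0:
        raise ValueError(f"not enough error degrees of freedom: N-K-o = {N - K - o}")
    X_aug = np.column_stack([np.ones(N), problem.X])
    if not check_estimability(X_aug).is_estimable:
        raise EstimabilityError("[1 X] is rank deficient")
    proj, *_ = np.linalg.lstsq(X_aug, Z, rcond=None)
    Zc = Z - X_aug @ proj
    base = ols_fit(problem)
    crit0 = float(stats.chi2.ppf(1 - alpha, o))
    if base.sse <= EXACT_FIT_TOL * max(float(problem.y @ problem.y), EXACT_FIT_TOL):
        return TestResult("LM", 0.0, (o,), crit0, 1.0, alpha, False,
                          list(cand.reaction_ids))
    e = base.residuals
    omega = e ** 2
    M = ((N - K) / (N - K - o)) * (Zc.T * omega) @ Zc
    rhs = Zc.T @ e
    if not np.any(np.abs(M) > 0):
        raise EstimabilityError(
            "Zc' Omega Zc is zero: candidates carry no residual-correlated "
            "signal and residuals vanish")
    try:
        statistic = float(rhs @ np.linalg.solve(M, rhs))
    except np.linalg.LinAlgError:
        # M can lose rank when residuals are exactly zero on some balance
        # rows (e.g. rows orphaned by a removal); rhs is then orthogonal to
        # the null space of M, so the pseudoinverse statistic is exact.
        statistic = float(rhs @ np.linalg.pinv(M, hermitian=True) @ rhs)
    crit = float(stats.chi2.ppf(1 - alpha, o))
    p_value = float(stats.chi2.sf(statistic, o))
    return TestResult("LM", statistic, (o,), crit, p_value, alpha,
                      bool(statistic >= crit), list(cand.reaction_ids))


def _dependent_columns(X: np.ndarray, Z: np.ndarray,
                       ids: list[str]) -> list[str]:
    """Identify Z columns linearly dependent on [X, preceding Z columns]."""
    dependent = []
    current = X
    for j, name in enumerate(ids):
        trial = np.column_stack([current, Z[:, j]])
        if check_estimability(trial).is_estimable:
            current = trial
        else:
            dependent.append(name)
    return dependent
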