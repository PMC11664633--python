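"""Wald tests and pointwise confidence bands for the time-varying effects.

All tests and intervals share one variance anchor: the inverse of the
negative penalized Hessian at theta_hat stored on the fitted model. For a
penalized fit this is the Bayesian-style (non-sandwich) variance; pass a
model refit without penalty if frequentist unpenalized variances are
wanted.

Available hypotheses, per covariate j with coefficient block theta_j and
its K x K covariance V_j:

* **proportional hazards** (:func:`test_ph`) — H0: beta_j(t) constant,
  i.e. C theta_j = 0 for the (K-1) x K adjacent-difference contrast C;
  chi-square with K-1 df. The statistic is invariant to which contrast
  basis spans the constants' orthogonal complement.
* **zero effect** (:func:`test_zero`) — H0: beta_j(t) = 0 for all t, i.e.
  theta_j = 0; chi-square with K df.
* **pointwise** (:func:`test_pointwise`) — H0: beta_j(t) = 0 at each grid
  time separately; 1 df each, no multiplicity adjustment by default
  (optional Bonferroni across the grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FittedModel

__all__ = ["TestResult", "test_ph", "test_zero", "test_pointwise", "confint_tvef", "get_tvef"]


@dataclass
class TestResult:
    """A Wald test outcome (scalar, or per-time vectors for pointwise)."""

    covariate: str
    test_kind: str  # "ph" | "zero" | "pointwise"
    statistic: float | np.ndarray
    df: int
    p_value: float | np.ndarray
    times: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def _default_times(model: FittedModel) -> np.ndarray:
    # default grid: the basis construction support (distinct event times are
    # not stored on the model; the boundary-spanning knots give the range)
    lo, hi = model.basis.boundary
    return np.linspace(lo, hi, 100)


def adjacent_difference_contrast(K: int) -> np.ndarray:
    """(K-1) x K matrix of adjacent differences; annihilates constants."""
    return np.diff(np.eye(K), axis=0)


def _wald_quadratic(est: np.ndarray, cov: np.ndarray) -> tuple[float, int, list[str]]:
    """est' cov^-1 est with a rank-adjusted pseudo-inverse fallback."""
    notes: list[str] = []
    try:
        sol = np.linalg.solve(cov, est)
        stat = float(est @ sol)
        df = est.shape[0]
        if stat < 0:  # numerically indefinite; fall through to pinv
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        pinv = np.linalg.pinv(cov, rcond=1e-10)
        stat = float(est @ pinv @ est)
        df = int(np.linalg.matrix_rank(cov, tol=1e-10))
        notes.append("contrast covariance singular; generalized inverse with rank-adjusted df")
    return max(stat, 0.0), df, notes


def test_ph(model: FittedModel, covariate) -> TestResult:
    """Wald test of the proportional-hazards hypothesis for one covariate.

    H0: beta_j(t) is constant in t. Requires K >= 2 basis functions.
    """
    j = model.covariate_index(covariate)
    K = model.K
    if K < 2:
        raise ValueError("PH test needs K >= 2 basis functions (K=1 is already constant)")
    C = adjacent_difference_contrast(K)
    theta_j = model.theta_hat.theta[j]
    V = model.covariance_block(j)
    est = C @ theta_j
    stat, df, notes = _wald_quadratic(est, C @ V @ C.T)
    return TestResult(
        covariate=model.theta_hat.covariate_names[j],
        test_kind="ph",
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        notes=notes,
    )


def test_zero(model: FittedModel, covariate) -> TestResult:
    """Wald test of no effect at any time: H0 theta_j = 0 (K df)."""
    j = model.covariate_index(covariate)
    theta_j = model.theta_hat.theta[j]
    V = model.covariance_block(j)
    stat, df, notes = _wald_quadratic(theta_j, V)
    return TestResult(
        covariate=model.theta_hat.covariate_names[j],
        test_kind="zero",
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        notes=notes,
    )


def _pointwise_se(model: FittedModel, j: int, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B = model.basis.evaluate(times)  # (T, K)
    beta = B @ model.theta_hat.theta[j]
    V = model.covariance_block(j)
    var = np.einsum("tk,kl,tl->t", B, V, B)
    return beta, var


def test_pointwise(
    model: FittedModel, covariate, times=None, bonferroni: bool = False
) -> TestResult:
    """Pointwise Wald significance of beta_j(t) over a time grid (1 df each)."""
    j = model.covariate_index(covariate)
    times = _default_times(model) if times is None else np.atleast_1d(np.asarray(times, dtype=float))
    beta, var = _pointwise_se(model, j, times)
    notes = []
    bad = var <= 0
    if np.any(bad):
        notes.append(f"non-positive variance at {int(bad.sum())} grid time(s); statistic set to NaN there")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(bad, np.nan, beta**2 / var)
    pval = stats.chi2.sf(stat, 1)
    if bonferroni:
        pval = np.minimum(pval * times.shape[0], 1.0)
        notes.append("Bonferroni-adjusted across the grid")
    else:
        notes.append("no multiplicity adjustment across the grid")
    return TestResult(
        covariate=model.theta_hat.covariate_names[j],
        test_kind="pointwise",
        statistic=stat,
        df=1,
        p_value=pval,
        times=times,
        notes=notes,
    )


def confint_tvef(model: FittedModel, covariate, times=None, level: float = 0.95) -> pd.DataFrame:
    """Pointwise normal confidence band for beta_j(t).

    Returns a DataFrame with columns time, estimate, lower, upper on the log
    hazard-ratio scale.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    j = model.covariate_index(covariate)
    times = _default_times(model) if times is None else np.atleast_1d(np.asarray(times, dtype=float))
    beta, var = _pointwise_se(model, j, times)
    se = np.sqrt(np.maximum(var, 0.0))
    zq = stats.norm.ppf(0.5 * (1.0 + level))
    return pd.DataFrame(
        {
            "time": times,
            "estimate": beta,
            "lower": beta - zq * se,
            "upper": beta + zq * se,
        }
    )


def get_tvef(model: FittedModel, times) -> pd.DataFrame:
    """Estimated time-varying coefficients on a grid, log hazard-ratio scale.

    Rows are times (clamped to the basis range), columns are covariates.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    vals = model.theta_hat.beta_at(times)  # (T, p)
    return pd.DataFrame(vals, index=pd.Index(times, name="time"),
                        columns=model.theta_hat.covariate_names)
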