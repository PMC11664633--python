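"""Proximal Newton maximization of the (penalized) log-partial likelihood.

:func:`fit_coxtv` maximizes the unpenalized Breslow log-partial likelihood;
:func:`fit_coxtp` the penalized one; :func:`fit_path` fits a descending
lambda path with warm starts. The update solves

    (-H + tau * I) delta = g

for the ascent direction, where H is the (penalized) Hessian and tau >= 0 a
proximal damping that is zero whenever the system is safely positive
definite and escalates multiplicatively when it is not — the concave
objective makes plain Newton the common case and damping the fallback for
ill-conditioned information (near-degenerate binary covariates, tiny risk
sets late in follow-up). Step sizes come from backtracking line search under
the Armijo sufficient-increase condition. Every accepted step increases the
objective, so the iteration trace is non-decreasing by construction.

Fits are deterministic: theta starts at zero (the null model) and no
randomness enters anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .basis import SplineBasis
from .model_core import CoefficientMatrix, log_partial_likelihood
from .penalties import PenaltySpec, make_penalty, penalized_objective
from .survdata import RiskSetIndex, SurvivalDataset, build_risk_sets

__all__ = ["FitConfig", "FittedModel", "fit_coxtv", "fit_coxtp", "fit_path"]

logger = logging.getLogger("tvcox")


class ConvergenceError(RuntimeError):
    """The Newton system stayed intractable even under maximal damping."""


@dataclass
class FitConfig:
    """Optimizer knobs. Defaults are conservative and rarely need touching."""

    max_iter: int = 200
    tol: float = 1e-9  # relative objective-change stopping rule
    prox_tau: float | None = None  # None = adaptive damping, start at 0
    backtrack_shrink: float = 0.5
    armijo_c: float = 1e-4
    max_backtracks: int = 50
    tau_cap: float = 1e12
    init: np.ndarray | None = None  # starting theta (p x K); default zeros

    def __post_init__(self) -> None:
        if not 0 < self.backtrack_shrink < 1:
            raise ValueError("backtrack_shrink must be in (0, 1)")
        if not 0 < self.armijo_c < 1:
            raise ValueError("armijo_c must be in (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


@dataclass
class FittedModel:
    """A converged (or honestly-flagged) fit.

    ``info_matrix`` is the negative penalized Hessian at theta_hat;
    ``info_inverse`` its inverse — the variance anchor for all Wald tests
    and confidence bands downstream.
    """

    theta_hat: CoefficientMatrix
    penalty: PenaltySpec
    info_matrix: np.ndarray
    info_inverse: np.ndarray
    trace: list[float]
    converged: bool
    n_iter: int
    final_grad_norm: float
    loglik: float  # unpenalized log-partial likelihood at theta_hat
    objective: float  # penalized objective at theta_hat
    messages: list[str] = field(default_factory=list)

    @property
    def basis(self) -> SplineBasis:
        return self.theta_hat.basis

    @property
    def p(self) -> int:
        return self.theta_hat.p

    @property
    def K(self) -> int:
        return self.theta_hat.K

    def covariate_index(self, covariate) -> int:
        if isinstance(covariate, (int, np.integer)):
            return int(covariate)
        names = self.theta_hat.covariate_names
        if covariate not in names:
            raise KeyError(f"unknown covariate {covariate!r}; have {names}")
        return names.index(covariate)

    def covariance_block(self, covariate) -> np.ndarray:
        """K x K block of info_inverse for one covariate."""
        j = self.covariate_index(covariate)
        K = self.K
        return self.info_inverse[j * K : (j + 1) * K, j * K : (j + 1) * K]


def _objective_at(theta, basis, names, data, risk, penalty, want):
    cm = CoefficientMatrix(theta, basis, list(names))
    ev = log_partial_likelihood(cm, data, risk, want=want)
    val, grad, hess = penalized_objective(cm, ev, penalty)
    return cm, ev, val, grad, hess


def _fit(
    data: SurvivalDataset,
    basis: SplineBasis,
    penalty: PenaltySpec,
    config: FitConfig,
    risk: RiskSetIndex | None = None,
) -> FittedModel:
    if risk is None:
        risk = build_risk_sets(data)
    p, K = data.p, basis.K
    names = data.covariate_names
    if config.init is not None:
        theta = np.array(config.init, dtype=float).reshape(p, K)
    else:
        theta = np.zeros((p, K))
    cm, ev, f, g, H = _objective_at(theta, basis, names, data, risk, penalty, "value_grad_hess")
    trace = [f]
    messages: list[str] = []
    tau = config.prox_tau if config.prox_tau is not None else 0.0
    converged = False
    n_iter = 0
    for it in range(config.max_iter):
        n_iter = it + 1
        A = -H
        # ascent direction from the (damped) Newton system
        delta = None
        while True:
            try:
                system = A if tau == 0.0 else A + tau * np.eye(p * K)
                cf = scipy.linalg.cho_factor(system, check_finite=False)
                delta = scipy.linalg.cho_solve(cf, g, check_finite=False)
                if g @ delta >= 0 and np.all(np.isfinite(delta)):
                    break
            except np.linalg.LinAlgError:
                pass
            except scipy.linalg.LinAlgError:
                pass
            tau = max(tau * 10.0, 1e-4 * max(np.max(np.diag(A)), 1e-4), 1e-8)
            if tau > config.tau_cap:
                raise ConvergenceError(
                    "Newton system is singular even under maximal proximal "
                    "damping; the information matrix is ill-conditioned "
                    "(consider a penalized fit or fewer basis functions)"
                )
        slope = float(g @ delta)
        # backtracking under the Armijo sufficient-increase condition
        step = 1.0
        accepted = False
        for _ in range(config.max_backtracks):
            theta_new = theta + step * delta.reshape(p, K)
            cm_new, ev_new, f_new, _, _ = _objective_at(
                theta_new, basis, names, data, risk, penalty, "value"
            )
            if np.isfinite(f_new) and f_new >= f + config.armijo_c * step * slope:
                accepted = True
                break
            step *= config.backtrack_shrink
        grad_norm = float(np.max(np.abs(g)))
        if not accepted:
            if grad_norm < 1e-5:
                converged = True
                messages.append(
                    f"line search stalled at small gradient (max|g|={grad_norm:.2e}); "
                    "treating as converged"
                )
                break
            tau = max(tau * 10.0, 1e-4 * max(np.max(np.diag(A)), 1e-4), 1e-8)
            if tau > config.tau_cap:
                raise ConvergenceError(
                    "backtracking failed with a large gradient under maximal damping"
                )
            continue
        theta = theta_new
        cm, ev, f_prev = cm_new, ev_new, f
        cm, ev, f, g, H = _objective_at(theta, basis, names, data, risk, penalty, "value_grad_hess")
        trace.append(f)
        if abs(f - f_prev) <= config.tol * (1.0 + abs(f)):
            converged = True
            break
    final_grad_norm = float(np.max(np.abs(g)))
    if not converged:
        messages.append(
            f"stopped at max_iter={config.max_iter} with max|g|={final_grad_norm:.2e}"
        )
        logger.warning("fit did not converge: %s", messages[-1])
    info = -H
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        info_inv = np.linalg.pinv(info)
        messages.append("information matrix singular; variance uses a pseudo-inverse")
        logger.warning(messages[-1])
    logger.info(
        "fit: %d iterations, objective %.6f, max|g|=%.2e, converged=%s",
        n_iter, f, final_grad_norm, converged,
    )
    return FittedModel(
        theta_hat=cm,
        penalty=penalty,
        info_matrix=info,
        info_inverse=info_inv,
        trace=trace,
        converged=converged,
        n_iter=n_iter,
        final_grad_norm=final_grad_norm,
        loglik=ev.loglik,
        objective=f,
        messages=messages,
    )


def fit_coxtv(
    data: SurvivalDataset,
    basis: SplineBasis | None = None,
    config: FitConfig | None = None,
) -> FittedModel:
    """Unpenalized maximum partial-likelihood fit of the time-varying model.

    ``basis`` defaults to a cubic basis with K=8 functions on the distinct
    event times.
    """
    if basis is None:
        basis = _default_basis(data)
    config = config or FitConfig()
    return _fit(data, basis, PenaltySpec(kind="none"), config)


def fit_coxtp(
    data: SurvivalDataset,
    basis: SplineBasis | None = None,
    penalty: PenaltySpec | None = None,
    config: FitConfig | None = None,
) -> FittedModel:
    """Penalized fit; ``lambda=0`` reproduces :func:`fit_coxtv` exactly."""
    if basis is None:
        basis = _default_basis(data)
    if penalty is None:
        penalty = make_penalty("pspline", basis, lam=1.0)
    config = config or FitConfig()
    return _fit(data, basis, penalty, config)


def fit_path(
    data: SurvivalDataset,
    basis: SplineBasis,
    penalty_kind: str,
    lambdas,
    config: FitConfig | None = None,
    diff_order: int = 2,
    deriv_order: int | None = None,
) -> list[FittedModel]:
    """Fit a lambda path, sorted descending, warm-starting each fit.

    Returns one FittedModel per lambda in descending-lambda order; each
    fit's solution initializes the next (smaller) lambda. If a fit fails,
    the rest of the path is still attempted and a single error naming the
    failing lambda values is raised at the end.
    """
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    if np.any(lambdas < 0):
        raise ValueError("all lambdas must be >= 0")
    config = config or FitConfig()
    base = make_penalty(penalty_kind, basis, lam=0.0, diff_order=diff_order, deriv_order=deriv_order)
    models: list[FittedModel] = []
    init = config.init
    failures: list[tuple[float, Exception]] = []
    for lam in lambdas:
        cfg = FitConfig(
            max_iter=config.max_iter,
            tol=config.tol,
            prox_tau=config.prox_tau,
            backtrack_shrink=config.backtrack_shrink,
            armijo_c=config.armijo_c,
            max_backtracks=config.max_backtracks,
            tau_cap=config.tau_cap,
            init=init,
        )
        try:
            model = _fit(data, basis, base.with_lambda(float(lam)), cfg)
        except ConvergenceError as exc:  # keep walking the path
            failures.append((float(lam), exc))
            continue
        models.append(model)
        init = model.theta_hat.theta
    if failures:
        lams = ", ".join(f"{lam:g}" for lam, _ in failures)
        raise ConvergenceError(
            f"path fits failed at lambda in {{{lams}}}: {failures[0][1]}"
        )
    return models


def _default_basis(data: SurvivalDataset, K: int = 8, degree: int = 3) -> SplineBasis:
    from .basis import make_basis

    distinct = np.unique(data.time[data.event == 1])
    k = K
    while k > degree + 1 and distinct.shape[0] - 2 < k - degree - 1:
        k -= 1
    return make_basis(distinct, K=k, degree=degree)
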