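"""Log-partial likelihood with time-varying coefficients: value, gradient, Hessian.

The model is a Cox non-proportional hazards model with hazard
lambda(t | z) = lambda_0s(t) * exp(z' beta(t)) for a subject in stratum s,
where each coordinate of beta(t) is spanned by a shared B-spline basis,
beta_j(t) = sum_k theta_jk B_k(t). Ties are handled with the Breslow
approximation: for each stratum and distinct event time t_m with tie set
D_m (size d_m) and risk set R_m, the log-partial likelihood contributes

    sum_{i in D_m} eta_i(t_m) - d_m * log sum_{l in R_m} exp(eta_l(t_m)),

with eta_i(t) = z_i' beta(t) = (z_i kron B(t))' vec(theta). The flattening
of theta is covariate-major: vec(theta) = theta.ravel() for theta of shape
(p, K) — all K basis coefficients of covariate 1 first. Gradient and
Hessian are exact derivatives of this sum, accumulated event time by event
time through the Kronecker structure of x_i(t) = z_i kron B(t): per event
time only a p-vector/p x p moment of z over the risk set and the K-vector
B(t_m) are combined, never an n x pK expanded design.

Every risk-set sum is computed with log-sum-exp stabilization; extreme
linear predictors degrade gracefully instead of overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import SplineBasis
from .survdata import RiskSetIndex, SurvivalDataset

__all__ = [
    "CoefficientMatrix",
    "LikelihoodEvaluation",
    "log_partial_likelihood",
    "linear_predictor",
    "score_outer_information",
]


@dataclass
class CoefficientMatrix:
    """theta, p x K: row j spans beta_j(t) = sum_k theta_jk B_k(t)."""

    theta: np.ndarray
    basis: SplineBasis
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if self.theta.shape[1] != self.basis.K:
            raise ValueError(
                f"theta has {self.theta.shape[1]} columns but the basis has "
                f"K={self.basis.K} functions"
            )
        if not self.covariate_names:
            self.covariate_names = [f"z{j + 1}" for j in range(self.theta.shape[0])]

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    def vec(self) -> np.ndarray:
        """Covariate-major flattening; inverse of :meth:`from_vec`."""
        return self.theta.ravel()

    @classmethod
    def from_vec(cls, v, basis: SplineBasis, p: int, covariate_names=None):
        v = np.asarray(v, dtype=float)
        return cls(
            theta=v.reshape(p, basis.K),
            basis=basis,
            covariate_names=list(covariate_names) if covariate_names else [],
        )

    def beta_at(self, times, clamp: bool = True) -> np.ndarray:
        """beta(t) on a grid: shape (len(times), p)."""
        B = self.basis.evaluate(times, clamp=clamp)
        return B @ self.theta.T


@dataclass
class LikelihoodEvaluation:
    """Value / gradient / Hessian of the log-partial likelihood at one theta."""

    loglik: float
    gradient: np.ndarray | None = None  # length pK, covariate-major
    hessian: np.ndarray | None = None  # pK x pK, symmetric, NSD
    per_stratum: dict = field(default_factory=dict)


_WANTS = ("value", "value_grad", "value_grad_hess")


def log_partial_likelihood(
    cm: CoefficientMatrix,
    data: SurvivalDataset,
    risk: RiskSetIndex,
    want: str = "value_grad_hess",
) -> LikelihoodEvaluation:
    """Breslow log-partial likelihood and its exact derivatives in vec(theta).

    The Hessian of each event-time term is -d_m times a softmax-weighted
    covariance of x_l(t_m) over the risk set, hence negative semidefinite
    everywhere; the total log-partial likelihood is concave in vec(theta).
    """
    if want not in _WANTS:
        raise ValueError(f"want must be one of {_WANTS}")
    theta = cm.theta
    p, K = theta.shape
    if p != data.p:
        raise ValueError(f"theta has {p} covariate rows but data has p={data.p}")
    pk = p * K
    need_grad = want != "value"
    need_hess = want == "value_grad_hess"
    ll = 0.0
    grad = np.zeros(pk) if need_grad else None
    hess = np.zeros((pk, pk)) if need_hess else None
    per_stratum: dict = {}
    for s in risk.strata:
        M = s.event_times.shape[0]
        if M == 0:
            per_stratum[s.label] = 0.0
            continue
        zs = data.z[s.order]  # subjects sorted by descending time
        Bm = cm.basis.evaluate(s.event_times)  # (M, K)
        eta = zs @ (theta @ Bm.T)  # (n_s, M)
        ll_s = 0.0
        for m in range(M):
            r = s.n_at_risk[m]
            d = s.d[m]
            col = eta[:r, m]
            cmax = col.max()
            ew = np.exp(col - cmax)
            sew = ew.sum()
            ll_s += eta[s.tie_pos[m], m].sum() - d * (cmax + np.log(sew))
            if not need_grad:
                continue
            B = Bm[m]
            w = ew / sew  # softmax weights over the risk set
            zr = zs[:r]
            sbar = zr.T @ w  # weighted mean of z at risk, length p
            g_z = zs[s.tie_pos[m]].sum(axis=0) - d * sbar
            grad += np.outer(g_z, B).ravel()
            if need_hess:
                A = zr.T @ (w[:, None] * zr)  # weighted second moment, p x p
                xbar = np.outer(sbar, B).ravel()
                hess -= d * (np.kron(A, np.outer(B, B)) - np.outer(xbar, xbar))
        ll += ll_s
        per_stratum[s.label] = ll_s
    if need_hess:
        hess = 0.5 * (hess + hess.T)  # enforce exact symmetry
    return LikelihoodEvaluation(
        loglik=ll, gradient=grad, hessian=hess, per_stratum=per_stratum
    )


def score_outer_information(
    cm: CoefficientMatrix, data: SurvivalDataset, risk: RiskSetIndex
) -> np.ndarray:
    """Outer-product (score-based) information J = sum_m u_m u_m'.

    u_m is the gradient contribution of the m-th event time (pooled over
    strata in their own event-time grids). Used by the generalized
    information criterion; equals minus the Hessian in expectation under a
    well-specified model but not in finite samples.
    """
    theta = cm.theta
    p, K = theta.shape
    J = np.zeros((p * K, p * K))
    for s in risk.strata:
        M = s.event_times.shape[0]
        if M == 0:
            continue
        zs = data.z[s.order]
        Bm = cm.basis.evaluate(s.event_times)
        eta = zs @ (theta @ Bm.T)
        for m in range(M):
            r = s.n_at_risk[m]
            d = s.d[m]
            col = eta[:r, m]
            ew = np.exp(col - col.max())
            w = ew / ew.sum()
            sbar = zs[:r].T @ w
            g_z = zs[s.tie_pos[m]].sum(axis=0) - d * sbar
            u = np.outer(g_z, Bm[m]).ravel()
            J += np.outer(u, u)
    return J


def linear_predictor(cm: CoefficientMatrix, z_row, t: float) -> float:
    """eta(t) = z' beta(t) for one subject at one time (clamped to range)."""
    z_row = np.asarray(z_row, dtype=float).ravel()
    B = cm.basis.evaluate([t])[0]
    return float(z_row @ (cm.theta @ B))
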