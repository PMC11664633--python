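"""Quadratic roughness penalties on the basis coefficients.

Two penalty families, both of the form lambda * sum_j theta_j' S theta_j
with a single K x K symmetric PSD matrix S shared by all covariates:

* **P-spline** — discrete penalty on differences of adjacent basis
  coefficients, S = D_d' D_d with D_d the d-th order difference operator.
  Order-1 differences vanish on constant coefficient vectors, so as
  lambda -> infinity the fitted effects become constant in t; order 2
  (the default) additionally spares coefficient sequences linear in the
  basis index.
* **Smoothing spline** — derivative penalty
  S_kl = integral B_k^(r)(t) B_l^(r)(t) dt over the basis range. With a
  cubic basis the second derivative is penalized (lambda -> infinity
  shrinks beta_j(t) to a straight line); with a quadratic basis the first
  derivative is penalized (limit: constant effect). The integrand is
  piecewise polynomial, so fixed Gauss-Legendre quadrature per knot
  interval is exact.

The penalized objective is loglik - lambda * sum_j theta_j' S theta_j; its
gradient subtracts 2*lambda*S theta_j per covariate block and its Hessian
subtracts 2*lambda*blockdiag(S,...,S) under the covariate-major flattening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import SplineBasis
from .model_core import CoefficientMatrix, LikelihoodEvaluation

__all__ = [
    "PenaltySpec",
    "pspline_matrix",
    "smoothing_spline_matrix",
    "make_penalty",
    "penalty_block",
    "penalized_objective",
]

PENALTY_KINDS = ("none", "pspline", "smoothing_spline")


@dataclass
class PenaltySpec:
    """Penalty kind, tuning parameter and assembled K x K matrix."""

    kind: str = "none"
    lam: float = 0.0
    diff_order: int = 2  # P-spline difference order
    deriv_order: int | None = None  # smoothing-spline derivative order
    S: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in PENALTY_KINDS:
            raise ValueError(f"penalty kind must be one of {PENALTY_KINDS}")
        if self.lam < 0:
            raise ValueError("penalty tuning parameter lambda must be >= 0")

    def with_lambda(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(
            kind=self.kind,
            lam=lam,
            diff_order=self.diff_order,
            deriv_order=self.deriv_order,
            S=self.S,
        )


def pspline_matrix(K: int, diff_order: int = 2) -> np.ndarray:
    """S = D'D for the d-th order difference operator D of size (K-d) x K.

    rank(S) = K - d; the null space holds polynomial-in-index coefficient
    sequences up to degree d-1 (d=1: constants; d=2: constants and linears).
    """
    if diff_order < 1:
        raise ValueError("difference order must be >= 1")
    if diff_order >= K:
        raise ValueError(f"difference order {diff_order} must be < K={K}")
    D = np.diff(np.eye(K), n=diff_order, axis=0)
    return D.T @ D


def smoothing_spline_matrix(basis: SplineBasis, deriv_order: int | None = None) -> np.ndarray:
    """Gram matrix of r-th basis derivatives, integrated over the range.

    ``deriv_order`` defaults to 2 for degree >= 3 and 1 otherwise. The
    integrand B_k^(r) B_l^(r) has piecewise degree 2*(degree - r), so
    Gauss-Legendre with degree - r + 2 nodes per knot interval is exact.
    """
    r = deriv_order
    if r is None:
        r = 2 if basis.degree >= 3 else 1
    if r < 1:
        raise ValueError("derivative order must be >= 1")
    if r > basis.degree:
        raise ValueError(
            f"derivative order {r} exceeds basis degree {basis.degree}"
        )
    breakpoints = np.unique(basis.knots)
    n_nodes = basis.degree - r + 2
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    K = basis.K
    S = np.zeros((K, K))
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        half = 0.5 * (b - a)
        nodes = a + half * (x + 1.0)
        Bd = basis.derivative(nodes, order=r)  # (n_nodes, K)
        S += half * (Bd.T @ (w[:, None] * Bd))
    return 0.5 * (S + S.T)


def make_penalty(
    kind: str,
    basis: SplineBasis,
    lam: float = 0.0,
    diff_order: int = 2,
    deriv_order: int | None = None,
) -> PenaltySpec:
    """Assemble a :class:`PenaltySpec` with its matrix for the given basis."""
    if kind == "none":
        return PenaltySpec(kind="none", lam=0.0, S=None)
    if kind == "pspline":
        S = pspline_matrix(basis.K, diff_order)
        return PenaltySpec(kind="pspline", lam=lam, diff_order=diff_order, S=S)
    if kind == "smoothing_spline":
        r = deriv_order if deriv_order is not None else (2 if basis.degree >= 3 else 1)
        S = smoothing_spline_matrix(basis, r)
        return PenaltySpec(kind="smoothing_spline", lam=lam, deriv_order=r, S=S)
    raise ValueError(f"unknown penalty kind {kind!r}")


def penalty_block(spec: PenaltySpec, p: int) -> np.ndarray:
    """blockdiag(S, ..., S) (p blocks) under the covariate-major flattening."""
    if spec.kind == "none" or spec.S is None or spec.lam == 0.0:
        K = 1 if spec.S is None else spec.S.shape[0]
        return np.zeros((p * K, p * K))
    return np.kron(np.eye(p), spec.S)


def penalized_objective(
    cm: CoefficientMatrix,
    ev: LikelihoodEvaluation,
    spec: PenaltySpec,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """(value, gradient, hessian) of loglik - lambda * sum_j theta_j' S theta_j.

    ``ev`` must have been computed at ``cm``; pieces absent from ``ev``
    (gradient/Hessian) come back as None. lambda = 0 or kind "none" returns
    the unpenalized evaluation unchanged.
    """
    if spec.kind == "none" or spec.lam == 0.0 or spec.S is None:
        return ev.loglik, ev.gradient, ev.hessian
    theta = cm.theta
    St = theta @ spec.S  # (p, K): row j = S theta_j (S symmetric)
    value = ev.loglik - spec.lam * float(np.sum(theta * St))
    grad = None if ev.gradient is None else ev.gradient - 2.0 * spec.lam * St.ravel()
    hess = None
    if ev.hessian is not None:
        hess = ev.hessian - 2.0 * spec.lam * np.kron(np.eye(cm.p), spec.S)
    return value, grad, hess
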