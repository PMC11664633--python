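"""Tuning-parameter selection: information criteria and cross-validation.

Information criteria (:func:`information_criteria`) use the standard
penalized-likelihood degrees-of-freedom constructions. With l the
unpenalized log-partial likelihood at theta_hat(lambda), H the unpenalized
negative Hessian there, P = H + 2*lambda*blockdiag(S) the penalized negative
Hessian, and J the outer-product (score-based) information:

    mAIC = -2 l + 2 tr(P^-1 H)          effective_df = tr(P^-1 H)
    TIC  = -2 l + 2 tr(P^-1 H P^-1 H)
    GIC  = -2 l + 2 tr(P^-1 J)

At lambda = 0 all traces collapse to pK and mAIC is the classical AIC.
Smaller is better; criterion ties resolve to the larger lambda (prefer the
smoother fit).

Cross-validation (:func:`cross_validate`) scores each lambda by the
cross-validated partial likelihood in the Verweij-van Houwelingen form:
each fold contributes l_full(theta_train) - l_train(theta_train), which
sidesteps the degenerate risk sets a small held-out fold would have on its
own. Folds are assigned by a seeded shuffle stratified on the event
indicator (and stratum), so event counts stay balanced. Larger summed
contribution is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import SplineBasis
from .fitting import FitConfig, FittedModel, fit_path
from .model_core import log_partial_likelihood, score_outer_information
from .penalties import make_penalty
from .survdata import SurvivalDataset, build_risk_sets

__all__ = ["TuningResult", "default_lambda_grid", "information_criteria", "cross_validate"]

CRITERIA = ("mAIC", "TIC", "GIC")


def default_lambda_grid(n_points: int = 20, lo: float = 1e-3, hi: float = 1e3) -> np.ndarray:
    """Log-spaced lambda grid, descending."""
    return np.logspace(np.log10(hi), np.log10(lo), n_points)


@dataclass
class TuningResult:
    """Criterion values over the lambda path and the selected models.

    ``criterion_values`` has one row per lambda (descending); columns are
    criteria (IC) or folds (CV). ``selected`` maps a criterion name to
    ``(lambda, FittedModel)``.
    """

    lambdas: np.ndarray
    criterion_values: np.ndarray
    criterion_names: list[str]
    selected: dict = field(default_factory=dict)
    effective_df: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    def selected_lambda(self, criterion: str) -> float:
        return self.selected[criterion][0]

    def selected_model(self, criterion: str) -> FittedModel:
        return self.selected[criterion][1]


def information_criteria(path: list[FittedModel], data: SurvivalDataset) -> TuningResult:
    """mAIC / TIC / GIC along a fitted lambda path.

    All models must share the data, basis and penalty kind (as produced by
    :func:`tvcox.fitting.fit_path`). A lambda whose penalized information is
    numerically singular gets NaN criteria and a diagnostic note.
    """
    if not path:
        raise ValueError("empty model path")
    risk = build_risk_sets(data)
    lambdas = np.array([m.penalty.lam for m in path])
    order = np.argsort(-lambdas, kind="stable")
    path = [path[i] for i in order]
    lambdas = lambdas[order]
    vals = np.full((len(path), 3), np.nan)
    eff_df = np.full(len(path), np.nan)
    notes: list[str] = []
    for i, m in enumerate(path):
        ev = log_partial_likelihood(m.theta_hat, data, risk, want="value_grad_hess")
        H = -ev.hessian
        P = m.info_matrix  # H + penalty block, computed at theta_hat
        try:
            PiH = np.linalg.solve(P, H)
        except np.linalg.LinAlgError:
            notes.append(
                f"lambda={m.penalty.lam:g}: penalized information singular; "
                "criteria unavailable"
            )
            continue
        J = score_outer_information(m.theta_hat, data, risk)
        df = float(np.trace(PiH))
        eff_df[i] = df
        l = ev.loglik
        vals[i, 0] = -2.0 * l + 2.0 * df
        vals[i, 1] = -2.0 * l + 2.0 * float(np.trace(PiH @ PiH))
        vals[i, 2] = -2.0 * l + 2.0 * float(np.trace(np.linalg.solve(P, J)))
    selected = {}
    for c, name in enumerate(CRITERIA):
        col = vals[:, c]
        if np.all(np.isnan(col)):
            continue
        best = np.nanmin(col)
        # ties -> larger lambda; path is descending, so take the first hit
        idx = int(np.flatnonzero(np.isclose(col, best, rtol=0, atol=0) | (col == best))[0])
        selected[name] = (float(lambdas[idx]), path[idx])
    return TuningResult(
        lambdas=lambdas,
        criterion_values=vals,
        criterion_names=list(CRITERIA),
        selected=selected,
        effective_df=eff_df,
        notes=notes,
    )


def _assign_folds(data: SurvivalDataset, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold labels after a shuffle within each (stratum, event) cell."""
    folds = np.empty(data.n, dtype=np.int64)
    strat = data.stratum if data.stratum is not None else np.zeros(data.n, dtype=np.int64)
    for s in np.unique(strat):
        for e in (0, 1):
            rows = np.flatnonzero((strat == s) & (data.event == e))
            rows = rng.permutation(rows)
            folds[rows] = np.arange(rows.shape[0]) % n_folds
    return folds


def _folds_valid(data: SurvivalDataset, folds: np.ndarray, n_folds: int) -> bool:
    strat = data.stratum if data.stratum is not None else np.zeros(data.n, dtype=np.int64)
    for f in range(n_folds):
        train = folds != f
        for s in np.unique(strat):
            if data.event[train & (strat == s)].sum() < 1:
                return False
    return True


def cross_validate(
    data: SurvivalDataset,
    basis: SplineBasis,
    penalty_kind: str,
    lambdas,
    n_folds: int = 5,
    seed: int = 0,
    config: FitConfig | None = None,
    diff_order: int = 2,
    deriv_order: int | None = None,
) -> TuningResult:
    """K-fold cross-validated partial likelihood over a lambda grid.

    Deterministic given ``seed``. The selected lambda maximizes the summed
    Verweij-van Houwelingen contribution; ties resolve to the larger
    lambda.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    rng = np.random.default_rng(seed)
    folds = _assign_folds(data, n_folds, rng)
    attempts = 1
    while not _folds_valid(data, folds, n_folds):
        if attempts >= 20:
            raise ValueError(
                "could not build folds with >=1 training event per stratum "
                f"in {attempts} attempts; reduce n_folds"
            )
        folds = _assign_folds(data, n_folds, rng)
        attempts += 1
    risk_full = build_risk_sets(data)
    contrib = np.zeros((lambdas.shape[0], n_folds))
    for f in range(n_folds):
        train = data.subset(np.flatnonzero(folds != f))
        models = fit_path(
            train, basis, penalty_kind, lambdas, config=config,
            diff_order=diff_order, deriv_order=deriv_order,
        )
        risk_train = build_risk_sets(train)
        for i, m in enumerate(models):
            l_full = log_partial_likelihood(m.theta_hat, data, risk_full, want="value").loglik
            l_train = log_partial_likelihood(m.theta_hat, train, risk_train, want="value").loglik
            contrib[i, f] = l_full - l_train
    cvl = contrib.sum(axis=1)
    idx = int(np.flatnonzero(cvl == cvl.max())[0])  # descending path: first = larger lambda
    penalty = make_penalty(
        penalty_kind, basis, lam=float(lambdas[idx]),
        diff_order=diff_order, deriv_order=deriv_order,
    )
    from .fitting import fit_coxtp

    best = fit_coxtp(data, basis, penalty, config)
    return TuningResult(
        lambdas=lambdas,
        criterion_values=contrib,
        criterion_names=[f"fold{f}" for f in range(n_folds)],
        selected={"cvl": (float(lambdas[idx]), best)},
        notes=[f"fold assignment attempts: {attempts}"],
    )
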