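"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive — double loops, explicit expanded
design matrices, textbook recursions — and shares no code path with the
package's Kronecker-structured accumulation.
"""

from __future__ import annotations

import numpy as np


def naive_breslow_loglik(theta, data, basis):
    """Breslow log-partial likelihood by explicit double loops.

    theta: (p, K). Iterates subjects and risk sets directly on the raw
    arrays; no sorting, no prefix structure, no log-sum-exp.
    """
    theta = np.atleast_2d(theta)
    strat = data.stratum if data.stratum is not None else np.zeros(data.n, dtype=int)
    ll = 0.0
    for s in np.unique(strat):
        rows = np.flatnonzero(strat == s)
        times = data.time[rows]
        events = data.event[rows]
        for tm in np.unique(times[events == 1]):
            B = basis.evaluate([tm])[0]
            beta = theta @ B  # (p,)
            tie = rows[(times == tm) & (events == 1)]
            at_risk = rows[times >= tm]
            num = sum(float(data.z[i] @ beta) for i in tie)
            den = sum(np.exp(float(data.z[i] @ beta)) for i in at_risk)
            ll += num - len(tie) * np.log(den)
    return ll


def expanded_design(data, basis):
    """Counting-process expansion: per (stratum, event time), the risk-set
    rows of the pK design x_i = kron(z_i, B(t_m)) plus the tie information.

    Returns a list of (X_risk, x_tie_sum, d) triples.
    """
    p, K = data.p, basis.K
    strat = data.stratum if data.stratum is not None else np.zeros(data.n, dtype=int)
    parts = []
    for s in np.unique(strat):
        rows = np.flatnonzero(strat == s)
        times = data.time[rows]
        events = data.event[rows]
        for tm in np.unique(times[events == 1]):
            B = basis.evaluate([tm])[0]
            tie = rows[(times == tm) & (events == 1)]
            at_risk = rows[times >= tm]
            X = np.stack([np.kron(data.z[i], B) for i in at_risk])
            x_tie = np.sum([np.kron(data.z[i], B) for i in tie], axis=0)
            parts.append((X, x_tie, len(tie)))
    return parts


def expanded_loglik_grad_hess(vec_theta, parts):
    """Value/gradient/Hessian from the explicit expanded design."""
    pk = vec_theta.shape[0]
    ll = 0.0
    g = np.zeros(pk)
    H = np.zeros((pk, pk))
    for X, x_tie, d in parts:
        eta = X @ vec_theta
        emax = eta.max()
        w_un = np.exp(eta - emax)
        den = w_un.sum()
        ll += x_tie @ vec_theta - d * (emax + np.log(den))
        w = w_un / den
        xbar = X.T @ w
        g += x_tie - d * xbar
        H -= d * ((X.T * w) @ X - np.outer(xbar, xbar))
    return ll, g, H


def expanded_newton_fit(data, basis, S=None, lam=0.0, max_iter=200, tol=1e-11):
    """Dense Newton on the counting-process-expanded design.

    Maximizes the (optionally penalized) Breslow log-partial likelihood with
    ridge-damped Newton steps and simple step halving. S is the K x K
    penalty matrix applied per covariate block; penalty = lam * theta_j'
    S theta_j summed over covariates.
    """
    p, K = data.p, basis.K
    pk = p * K
    parts = expanded_design(data, basis)
    if S is not None and lam > 0:
        P = lam * np.kron(np.eye(p), S)
    else:
        P = np.zeros((pk, pk))

    def objective(v):
        ll, g, H = expanded_loglik_grad_hess(v, parts)
        return ll - v @ P @ v, g - 2.0 * P @ v, H - 2.0 * P

    v = np.zeros(pk)
    f, g, H = objective(v)
    for _ in range(max_iter):
        A = -H
        ridge = 0.0
        while True:
            try:
                delta = np.linalg.solve(A + ridge * np.eye(pk), g)
                if g @ delta >= 0:
                    break
            except np.linalg.LinAlgError:
                pass
            ridge = max(ridge * 10.0, 1e-8)
        step = 1.0
        for _ in range(60):
            f_new, g_new, H_new = objective(v + step * delta)
            if np.isfinite(f_new) and f_new >= f:
                break
            step *= 0.5
        v = v + step * delta
        f_old, f, g, H = f, f_new, g_new, H_new
        if abs(f - f_old) <= tol * (1.0 + abs(f)):
            break
    return v.reshape(p, K), f


def cox_de_boor(knots, degree, K, t):
    """Textbook Cox-de Boor recursion for all K B-spline values at scalar t."""
    # zeroth degree: indicator of the half-open knot span, right-closed at the end
    n_b = len(knots) - 1
    N = np.zeros((degree + 1, n_b))
    for i in range(n_b):
        if knots[i] <= t < knots[i + 1] or (
            t == knots[-1] and knots[i] < knots[i + 1] and knots[i + 1] == knots[-1]
        ):
            N[0, i] = 1.0
    for d in range(1, degree + 1):
        for i in range(n_b - d):
            left = 0.0
            if knots[i + d] > knots[i]:
                left = (t - knots[i]) / (knots[i + d] - knots[i]) * N[d - 1, i]
            right = 0.0
            if knots[i + d + 1] > knots[i + 1]:
                right = (knots[i + d + 1] - t) / (knots[i + d + 1] - knots[i + 1]) * N[
                    d - 1, i + 1
                ]
            N[d, i] = left + right
    return N[degree, :K]


def naive_breslow_baseline(theta, data, basis):
    """Breslow increments d_m / sum_{at risk} exp(z' beta(t_m)), double loop.

    Single implicit stratum only (what the oracle tests need).
    """
    theta = np.atleast_2d(theta)
    out_t, out_inc = [], []
    for tm in np.unique(data.time[data.event == 1]):
        B = basis.evaluate([tm])[0]
        beta = theta @ B
        d = int(np.sum((data.time == tm) & (data.event == 1)))
        den = sum(
            np.exp(float(data.z[i] @ beta))
            for i in np.flatnonzero(data.time >= tm)
        )
        out_t.append(tm)
        out_inc.append(d / den)
    return np.asarray(out_t), np.asarray(out_inc)
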