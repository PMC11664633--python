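"""Breslow baseline hazard and survival prediction.

With theta_hat in hand, the cumulative baseline hazard of stratum s is the
Breslow step function with increments at each distinct event time t_m

    dLambda_0s(t_m) = d_m / sum_{l in R_m} exp(eta_hat_l(t_m)),

which at theta_hat = 0 reduces exactly to the (tied) Nelson-Aalen
estimator d_m / |R_m|. Survival prediction for a covariate vector z is the
right-continuous step function

    S(t | z) = exp( - sum_{t_m <= t} dLambda_0s(t_m) * exp(z' beta_hat(t_m)) ).

:func:`export_curves` emits a tidy long table of effect estimates with
confidence bands plus per-stratum cumulative hazards — the plotting
interface of the package (any front end can draw it).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .fitting import FittedModel
from .inference import confint_tvef
from .survdata import SurvivalDataset, build_risk_sets

__all__ = ["BaselineHazard", "baseline", "predict_survival", "export_curves"]

logger = logging.getLogger("tvcox")


@dataclass
class BaselineHazard:
    """Per-stratum cumulative baseline hazard as a step function."""

    stratum: object
    times: np.ndarray  # distinct event times, ascending
    increments: np.ndarray  # Breslow increments dLambda_0(t_m) > 0
    cumulative: np.ndarray  # running sum, non-decreasing

    def cumulative_at(self, times) -> np.ndarray:
        """Step-function value Lambda_0(t) at arbitrary times (0 before first event)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.cumulative])
        return padded[idx]


def baseline(model: FittedModel, data: SurvivalDataset) -> list[BaselineHazard]:
    """Breslow baseline hazard for every stratum of the fitted data."""
    risk = build_risk_sets(data)
    theta = model.theta_hat.theta
    out: list[BaselineHazard] = []
    for s in risk.strata:
        M = s.event_times.shape[0]
        if M == 0:
            logger.warning("stratum %r has no events; empty baseline", s.label)
            out.append(
                BaselineHazard(s.label, np.empty(0), np.empty(0), np.empty(0))
            )
            continue
        zs = data.z[s.order]
        Bm = model.basis.evaluate(s.event_times)  # (M, K)
        eta = zs @ (theta @ Bm.T)  # (n_s, M)
        inc = np.empty(M)
        for m in range(M):
            col = eta[: s.n_at_risk[m], m]
            cmax = col.max()
            inc[m] = s.d[m] * np.exp(-cmax) / np.exp(col - cmax).sum()
        out.append(
            BaselineHazard(
                stratum=s.label,
                times=s.event_times.copy(),
                increments=inc,
                cumulative=np.cumsum(inc),
            )
        )
    return out


def predict_survival(
    model: FittedModel, base: BaselineHazard, z_row, times
) -> np.ndarray:
    """S(t | z) on a grid; right-continuous, S(t) = 1 before the first event.

    Coefficient functions are clamped to the basis range, so hazard-ratio
    weights at event times beyond the last basis knot use the boundary
    value (constant extrapolation).
    """
    z_row = np.asarray(z_row, dtype=float).ravel()
    if z_row.shape[0] != model.p:
        raise ValueError(f"z has length {z_row.shape[0]} but the model has p={model.p}")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("prediction times must be >= 0")
    if base.times.shape[0] == 0:
        return np.ones_like(t)
    beta_ev = model.theta_hat.beta_at(base.times)  # (M, p), clamped
    weights = np.exp(beta_ev @ z_row)  # exp(z' beta(t_m))
    chz = np.cumsum(base.increments * weights)
    idx = np.searchsorted(base.times, t, side="right")
    padded = np.concatenate([[0.0], chz])
    return np.exp(-padded[idx])


def export_curves(
    model: FittedModel,
    baselines: list[BaselineHazard],
    times,
    level: float = 0.95,
    hazard_ratio: bool = False,
) -> pd.DataFrame:
    """Plot-ready long table of effect curves and baseline cumulative hazards.

    One row per (time, covariate) with the estimate and pointwise band on
    the log hazard-ratio scale (or HR scale with ``hazard_ratio=True``),
    followed by one row per (time, stratum) with the cumulative baseline
    hazard. Times beyond the basis range use the clamped (boundary) value
    of beta_hat; the ``clamped`` column flags them.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lo, hi = model.basis.boundary
    clamped = (times < lo) | (times > hi)
    blocks = []
    for name in model.theta_hat.covariate_names:
        ci = confint_tvef(model, name, times, level=level)
        df = pd.DataFrame(
            {
                "time": times,
                "kind": "effect",
                "label": name,
                "estimate": ci["estimate"],
                "lower": ci["lower"],
                "upper": ci["upper"],
                "clamped": clamped,
            }
        )
        if hazard_ratio:
            df[["estimate", "lower", "upper"]] = np.exp(df[["estimate", "lower", "upper"]])
        blocks.append(df)
    for base in baselines:
        blocks.append(
            pd.DataFrame(
                {
                    "time": times,
                    "kind": "baseline_cumhaz",
                    "label": str(base.stratum),
                    "estimate": base.cumulative_at(times),
                    "lower": np.nan,
                    "upper": np.nan,
                    "clamped": clamped,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)
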