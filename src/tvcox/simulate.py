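"""Synthetic right-censored survival data with known time-varying effects.

Event times are drawn from the hazard lambda(t | z) = lambda_0(t) *
exp(z' beta(t)) by inverting the subject-specific cumulative hazard on a
fine grid: the baseline cumulative hazard H_0 is known in closed form for
each supported family, the subject's cumulative hazard is accumulated as
sum over grid cells of exp(z' beta(t_mid)) * dH_0(cell), and an Exp(1) draw
is mapped back through linear interpolation. The grid (default 2000 cells
over [0, t_horizon]) is the only approximation; halving the step changes
the mean event time by well under 0.1% for the default settings.

Censoring is drawn independently (uniform, exponential or administrative);
follow-up is always truncated at ``t_horizon``. Optional rounding of the
observed times manufactures ties; a rounded time of zero triggers a
resample of that subject's event/censoring draw so all times stay positive.
Everything is deterministic given ``seed``.

The module also ships :func:`make_example_data` — a packaged two-covariate
tutorial dataset in which one covariate has a constant (proportional
hazards) effect and the other a sine-shaped, strongly time-varying effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .survdata import SurvivalDataset

__all__ = [
    "SimulationSpec",
    "simulate_dataset",
    "make_example_data",
    "constant",
    "linear",
    "sine",
    "decaying",
]


# ---------------------------------------------------------------- shapes

def constant(c: float) -> Callable[[np.ndarray], np.ndarray]:
    """beta(t) = c."""
    return lambda t: np.full_like(np.asarray(t, dtype=float), c)


def linear(a: float, b: float) -> Callable[[np.ndarray], np.ndarray]:
    """beta(t) = a + b t."""
    return lambda t: a + b * np.asarray(t, dtype=float)


def sine(amplitude: float, omega: float) -> Callable[[np.ndarray], np.ndarray]:
    """beta(t) = amplitude * sin(omega t)."""
    return lambda t: amplitude * np.sin(omega * np.asarray(t, dtype=float))


def decaying(c: float = 1.5, r: float = 0.35) -> Callable[[np.ndarray], np.ndarray]:
    """beta(t) = c * exp(-r t): a hazard ratio that is high early and fades.

    The defaults give a log hazard ratio of 1.5 (HR ~ 4.5) at diagnosis
    decaying to ~0.09 (HR ~ 1.1) by t = 8 — the typical trajectory of a
    late-stage-vs-early-stage cancer effect over eight years of follow-up.
    """
    return lambda t: c * np.exp(-r * np.asarray(t, dtype=float))


_SHAPES = {"constant": constant, "linear": linear, "sine": sine, "decaying": decaying}


def _as_beta(spec) -> Callable[[np.ndarray], np.ndarray]:
    if callable(spec):
        return spec
    name, *args = spec
    return _SHAPES[name](*args)


# ---------------------------------------------------------------- baselines

def _baseline_cumhaz(baseline) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form H_0(t) for the supported baseline families."""
    kind, *args = baseline
    if kind == "exponential":
        (rate,) = args
        return lambda t: rate * np.asarray(t, dtype=float)
    if kind == "weibull":
        shape, scale = args
        return lambda t: (np.asarray(t, dtype=float) / scale) ** shape
    if kind == "piecewise":
        rates, cuts = np.asarray(args[0], float), np.asarray(args[1], float)
        if rates.shape[0] != cuts.shape[0] + 1:
            raise ValueError("piecewise baseline needs len(rates) == len(cuts) + 1")
        edges = np.concatenate([[0.0], cuts])

        def H(t):
            t = np.asarray(t, dtype=float)
            out = np.zeros_like(t)
            for i, r in enumerate(rates):
                lo = edges[i]
                hi = edges[i + 1] if i + 1 < edges.shape[0] else np.inf
                out += r * np.clip(t - lo, 0.0, hi - lo)
            return out

        return H
    raise ValueError(f"unknown baseline family {kind!r}")


def _default_horizon(baseline) -> float:
    """Time at which the baseline cumulative hazard reaches 10."""
    kind, *args = baseline
    if kind == "exponential":
        return 10.0 / args[0]
    if kind == "weibull":
        shape, scale = args
        return scale * 10.0 ** (1.0 / shape)
    if kind == "piecewise":
        H = _baseline_cumhaz(baseline)
        t = 1.0
        while H(np.array([t]))[0] < 10.0 and t < 1e12:
            t *= 2.0
        return t
    raise ValueError(f"unknown baseline family {kind!r}")


# ---------------------------------------------------------------- spec

@dataclass
class SimulationSpec:
    """Study-design description for one synthetic dataset.

    ``beta_funcs`` accepts callables or named shapes like
    ``("sine", 1.0, 1.0)``; ``covariate_law`` entries are ``"normal"`` or
    ``("bernoulli", q)``. ``tie_rounding`` rounds observed times to that
    many decimals to manufacture ties (None = continuous times, ties have
    probability zero).
    """

    n: int = 1000
    p: int = 2
    covariate_law: Sequence = ("normal", "normal")
    beta_funcs: Sequence = (("constant", 1.0), ("sine", 1.0, 1.0))
    baseline: tuple = ("exponential", 1.0)
    censoring: tuple | None = ("uniform", 6.0)
    n_strata: int = 1
    stratum_multipliers: Sequence[float] | None = None
    tie_rounding: int | None = None
    t_horizon: float | None = None
    grid_points: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.covariate_law) != self.p or len(self.beta_funcs) != self.p:
            raise ValueError("covariate_law and beta_funcs must have length p")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")
        if self.stratum_multipliers is not None and len(self.stratum_multipliers) != self.n_strata:
            raise ValueError("need one baseline multiplier per stratum")


def _draw_covariates(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for law in spec.covariate_law:
        if law == "normal" or law == ("normal",):
            cols.append(rng.standard_normal(spec.n))
        else:
            kind, q = law
            if kind != "bernoulli":
                raise ValueError(f"unknown covariate law {law!r}")
            cols.append(rng.binomial(1, q, size=spec.n).astype(float))
    return np.column_stack(cols)


def _draw_censoring(spec: SimulationSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if spec.censoring is None:
        return np.full(size, np.inf)
    kind, *args = spec.censoring
    if kind == "uniform":
        return rng.uniform(0.0, args[0], size=size)
    if kind == "exponential":
        return rng.exponential(1.0 / args[0], size=size)
    if kind == "admin":
        return np.full(size, float(args[0]))
    raise ValueError(f"unknown censoring law {kind!r}")


def _invert_event_times(
    z: np.ndarray,
    mult: np.ndarray,
    betas: list[Callable],
    H0: Callable,
    grid: np.ndarray,
    e: np.ndarray,
) -> np.ndarray:
    """Map Exp(1) draws through the subject cumulative hazards; inf = beyond grid."""
    mids = 0.5 * (grid[:-1] + grid[1:])
    dH = np.diff(H0(grid))  # baseline increments per cell
    beta_mid = np.column_stack([b(mids) for b in betas])  # (G-1, p)
    n = z.shape[0]
    times = np.empty(n)
    chunk = max(1, int(5_000_000 // max(mids.shape[0], 1)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        eta = z[lo:hi] @ beta_mid.T  # (c, G-1)
        cum = np.cumsum(np.exp(eta) * dH, axis=1) * mult[lo:hi, None]
        cum0 = np.concatenate([np.zeros((hi - lo, 1)), cum], axis=1)  # at grid points
        ee = e[lo:hi]
        idx = np.sum(cum0 < ee[:, None], axis=1) - 1  # cell index: cum0[idx] <= e < cum0[idx+1]
        beyond = idx >= grid.shape[0] - 1
        idx = np.clip(idx, 0, grid.shape[0] - 2)
        rows = np.arange(hi - lo)
        c_lo = cum0[rows, idx]
        c_hi = cum0[rows, idx + 1]
        frac = np.where(c_hi > c_lo, (ee - c_lo) / np.where(c_hi > c_lo, c_hi - c_lo, 1.0), 1.0)
        t = grid[idx] + frac * (grid[idx + 1] - grid[idx])
        t[beyond] = np.inf
        times[lo:hi] = t
    return times


def simulate_dataset(spec: SimulationSpec):
    """Draw one dataset; returns ``(SurvivalDataset, truth)``.

    ``truth`` is the list of the p true coefficient functions as callables.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    betas = [_as_beta(b) for b in spec.beta_funcs]
    H0 = _baseline_cumhaz(spec.baseline)
    horizon = spec.t_horizon if spec.t_horizon is not None else _default_horizon(spec.baseline)
    grid = np.linspace(0.0, horizon, spec.grid_points + 1)
    z = _draw_covariates(spec, rng)
    if spec.n_strata > 1:
        stratum = rng.integers(0, spec.n_strata, size=spec.n)
        mults = np.asarray(
            spec.stratum_multipliers
            if spec.stratum_multipliers is not None
            else np.ones(spec.n_strata),
            dtype=float,
        )
        mult = mults[stratum]
    else:
        stratum = None
        mult = np.ones(spec.n)

    def draw(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        e = rng.exponential(size=rows.shape[0])
        T = _invert_event_times(z[rows], mult[rows], betas, H0, grid, e)
        C = np.minimum(_draw_censoring(spec, rng, rows.shape[0]), horizon)
        obs = np.minimum(T, C)
        event = (T <= C).astype(np.int64)
        return obs, event

    rows = np.arange(spec.n)
    time, event = draw(rows)
    if spec.tie_rounding is not None:
        time = np.round(time, spec.tie_rounding)
        # a time that rounds to zero is resampled until positive
        for _ in range(100):
            bad = np.flatnonzero(time <= 0)
            if bad.shape[0] == 0:
                break
            t_new, e_new = draw(bad)
            time[bad] = np.round(t_new, spec.tie_rounding)
            event[bad] = e_new
        else:
            raise RuntimeError("could not draw positive rounded times")
    frac = float(event.mean())
    if not 0.02 < frac < 0.98:
        warnings.warn(
            f"event fraction {frac:.3f} is outside (0.02, 0.98); "
            "check the censoring/horizon settings",
            stacklevel=2,
        )
    data = SurvivalDataset(
        z=z,
        time=time,
        event=event,
        stratum=None if stratum is None else stratum.astype(np.int64),
        covariate_names=[f"z{j + 1}" for j in range(spec.p)],
    )
    return data, betas


def example_spec(seed: int = 0, n: int = 2000) -> SimulationSpec:
    """The packaged tutorial design: one PH covariate, one sine-shaped effect.

    n subjects, two standard-normal covariates, beta_1(t) = 1 (constant,
    proportional hazards holds) and beta_2(t) = sin(pi t / 3) (rises to 1
    at mid follow-up, returns to 0), unit-rate exponential baseline,
    follow-up truncated at t = 3 and uniform censoring tuned for roughly a
    quarter of subjects censored overall.
    """
    return SimulationSpec(
        n=n,
        p=2,
        covariate_law=("normal", "normal"),
        beta_funcs=(("constant", 1.0), ("sine", 1.0, np.pi / 3.0)),
        baseline=("exponential", 1.0),
        censoring=("uniform", 6.0),
        t_horizon=3.0,
        seed=seed,
    )


def make_example_data(seed: int = 0, n: int = 2000) -> SurvivalDataset:
    """Simulate the packaged example dataset (see :func:`example_spec`)."""
    data, _ = simulate_dataset(example_spec(seed=seed, n=n))
    return data
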