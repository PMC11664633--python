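"""Right-censored survival data: container, validation, delimited I/O, risk sets.

The central object is :class:`SurvivalDataset`, a plain in-memory table of
``n`` subjects with a covariate matrix ``z`` (n x p), strictly positive
follow-up times, 0/1 event indicators and an optional stratum label.
:func:`build_risk_sets` materializes, per stratum, the distinct event times,
the tied-event sets and the at-risk sets that the partial likelihood sums
over.

Conventions (fixed here, relied on everywhere downstream):

* A subject censored at exactly an event time is still **in** that risk set
  (events precede censorings at tied times — the standard counting-process
  convention).
* Covariates are used as supplied; no internal standardization.
* Times are continuous reals; no binning on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "StratumRiskSets",
    "RiskSetIndex",
    "SchemaError",
    "DataValidationError",
    "load_dataset",
    "write_dataset",
    "dataset_from_frame",
    "build_risk_sets",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class DataValidationError(ValueError):
    """Values violate the survival-data invariants (non-positive time, ...)."""


@dataclass
class SurvivalDataset:
    """Subjects with covariates, follow-up times, event indicators, strata.

    Parameters
    ----------
    z
        Covariate matrix, shape ``(n, p)``. Continuous or binary; used as
        supplied.
    time
        Follow-up times, strictly positive, same units throughout.
    event
        Event indicators: 1 = observed event, 0 = right-censored.
    stratum
        Optional per-subject stratum labels; ``None`` means a single
        implicit stratum. Baseline hazards are stratum-specific while the
        coefficient functions are shared.
    covariate_names
        ``p`` labels, in column order of ``z``.
    """

    z: np.ndarray
    time: np.ndarray
    event: np.ndarray
    stratum: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.shape[0] == 1 and len(np.asarray(self.time).ravel()) > 1:
            self.z = self.z.T
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).ravel()
        n = self.time.shape[0]
        if self.z.shape[0] != n:
            raise DataValidationError(
                f"z has {self.z.shape[0]} rows but time has {n} entries"
            )
        if self.event.shape[0] != n:
            raise DataValidationError(
                f"event has {self.event.shape[0]} entries but time has {n}"
            )
        if not np.all(np.isfinite(self.z)):
            bad = int(np.argwhere(~np.isfinite(self.z))[0, 0])
            raise DataValidationError(f"non-finite covariate value in row {bad}")
        if not np.all(np.isfinite(self.time)):
            bad = int(np.flatnonzero(~np.isfinite(self.time))[0])
            raise DataValidationError(f"non-finite time in row {bad}")
        if np.any(self.time <= 0):
            bad = int(np.flatnonzero(self.time <= 0)[0])
            raise DataValidationError(
                f"non-positive follow-up time in row {bad} (time={self.time[bad]!r})"
            )
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            bad = int(np.flatnonzero(~np.isin(ev, (0.0, 1.0)))[0])
            raise DataValidationError(
                f"event indicator not in {{0,1}} in row {bad} (event={self.event[bad]!r})"
            )
        self.event = ev.astype(np.int64)
        if self.event.sum() == 0:
            raise DataValidationError(
                "no observed events: the partial likelihood is undefined"
            )
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum).ravel()
            if self.stratum.shape[0] != n:
                raise DataValidationError(
                    f"stratum has {self.stratum.shape[0]} entries but time has {n}"
                )
        if not self.covariate_names:
            self.covariate_names = [f"z{j + 1}" for j in range(self.z.shape[1])]
        if len(self.covariate_names) != self.z.shape[1]:
            raise DataValidationError(
                f"{len(self.covariate_names)} covariate names for {self.z.shape[1]} columns"
            )

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.z.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def stratum_labels(self) -> list:
        """Distinct stratum labels in first-appearance order."""
        if self.stratum is None:
            return [None]
        _, idx = np.unique(self.stratum, return_index=True)
        return [self.stratum[i] for i in np.sort(idx)]

    def subset(self, rows: np.ndarray) -> "SurvivalDataset":
        """Row subset (e.g. a cross-validation fold), preserving metadata."""
        rows = np.asarray(rows)
        return SurvivalDataset(
            z=self.z[rows],
            time=self.time[rows],
            event=self.event[rows],
            stratum=None if self.stratum is None else self.stratum[rows],
            covariate_names=list(self.covariate_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, columns=self.covariate_names)
        df["time"] = self.time
        df["event"] = self.event
        if self.stratum is not None:
            df["stratum"] = self.stratum
        return df


def dataset_from_frame(
    df: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    stratum_col: str | None = "stratum",
    covariate_cols: list[str] | None = None,
) -> SurvivalDataset:
    """Build a validated dataset from a DataFrame.

    By default every numeric column other than ``time``/``event``/``stratum``
    is a covariate, in the order given.
    """
    for col, what in ((time_col, "time"), (event_col, "event")):
        if col not in df.columns:
            raise SchemaError(f"required {what} column {col!r} not found")
    use_stratum = stratum_col is not None and stratum_col in df.columns
    if covariate_cols is None:
        reserved = {time_col, event_col} | ({stratum_col} if use_stratum else set())
        covariate_cols = [
            c
            for c in df.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(df[c])
        ]
    else:
        for c in covariate_cols:
            if c not in df.columns:
                raise SchemaError(f"covariate column {c!r} not found")
    if not covariate_cols:
        raise SchemaError("no covariate columns found")
    if df[covariate_cols].isna().any().any() or df[[time_col, event_col]].isna().any().any():
        bad = int(df[covariate_cols + [time_col, event_col]].isna().any(axis=1).idxmax())
        raise DataValidationError(f"missing value in row {bad}")
    return SurvivalDataset(
        z=df[covariate_cols].to_numpy(dtype=float),
        time=df[time_col].to_numpy(dtype=float),
        event=df[event_col].to_numpy(),
        stratum=df[stratum_col].to_numpy() if use_stratum else None,
        covariate_names=list(covariate_cols),
    )


def load_dataset(
    path,
    time_col: str = "time",
    event_col: str = "event",
    stratum_col: str | None = "stratum",
    covariate_cols: list[str] | None = None,
    delimiter: str = ",",
) -> SurvivalDataset:
    """Read a delimited text file with a header row into a validated dataset."""
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    return dataset_from_frame(df, time_col, event_col, stratum_col, covariate_cols)


def write_dataset(data: SurvivalDataset, path, delimiter: str = ",") -> None:
    """Write the dataset back out, round-trip safe to full double precision."""
    data.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


@dataclass
class StratumRiskSets:
    """Risk-set structure of one stratum.

    ``order`` sorts the stratum's subjects by descending follow-up time, so
    the at-risk set at the m-th (ascending) distinct event time is exactly
    the first ``n_at_risk[m]`` entries of the sorted arrays — risk sets are
    nested prefixes, which the likelihood code exploits.
    """

    label: object
    order: np.ndarray  # original row indices, time descending
    event_times: np.ndarray  # ascending distinct times with >=1 event
    d: np.ndarray  # tie multiplicities per event time
    n_at_risk: np.ndarray  # |{i : time_i >= t_m}| per event time
    tie_rows: list  # per event time: original row indices with event at t_m
    tie_pos: list  # same, as positions within `order`


@dataclass
class RiskSetIndex:
    """Per-stratum risk sets plus the pooled distinct event times."""

    strata: list[StratumRiskSets]
    pooled_event_times: np.ndarray  # ascending distinct event times, all strata


def build_risk_sets(data: SurvivalDataset) -> RiskSetIndex:
    """Materialize the risk sets the partial likelihood sums over.

    A subject whose censoring time equals an event time is counted at risk
    at that time. Strata with zero events contribute an empty structure.
    """
    strata: list[StratumRiskSets] = []
    for label in data.stratum_labels():
        if data.stratum is None:
            rows = np.arange(data.n)
        else:
            rows = np.flatnonzero(data.stratum == label)
        t = data.time[rows]
        e = data.event[rows]
        # stable descending-time sort
        order_local = np.argsort(-t, kind="stable")
        t_sorted = t[order_local]
        ev_times = np.unique(t[e == 1])  # ascending
        # at-risk count = number of sorted entries with time >= t_m
        n_at_risk = np.searchsorted(-t_sorted, -ev_times, side="right")
        tie_rows, tie_pos, d = [], [], []
        pos_of = np.empty(rows.shape[0], dtype=np.int64)
        pos_of[order_local] = np.arange(rows.shape[0])
        for tm in ev_times:
            local = np.flatnonzero((t == tm) & (e == 1))
            tie_rows.append(rows[local])
            tie_pos.append(pos_of[local])
            d.append(local.shape[0])
        strata.append(
            StratumRiskSets(
                label=label,
                order=rows[order_local],
                event_times=ev_times,
                d=np.asarray(d, dtype=np.int64),
                n_at_risk=n_at_risk.astype(np.int64),
                tie_rows=tie_rows,
                tie_pos=tie_pos,
            )
        )
    pooled = np.unique(data.time[data.event == 1])
    return RiskSetIndex(strata=strata, pooled_event_times=pooled)
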