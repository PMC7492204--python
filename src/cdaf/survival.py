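"""Kaplan-Meier estimation and the k-group log-rank test.

The log-rank statistic is accumulated per distinct event time from the
hypergeometric observed-minus-expected contributions, which is the form the
CART stage's dual significance gate recomputes.  Kaplan-Meier curves are
fitted with lifelines and re-exposed as a compact step-function container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    """A generic test statistic with its reference distribution's verdict."""

    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TestResult({self.method}: statistic={self.statistic:.4g}, "
            f"df={self.df}, p={self.p_value:.4g})"
        )


@dataclass
class SurvivalDataset:
    """Right-censored survival rows: (time, event) plus named covariates."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.size == 0:
            raise ValueError("survival dataset must have at least one row")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be finite and positive")
        if self.event.shape != self.time.shape:
            raise ValueError("time and event must have equal length")
        if len(self.covariates) not in (0, self.time.size):
            raise ValueError("covariate table length mismatch")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col: str = "time", event_col: str = "event"
    ) -> "SurvivalDataset":
        cov = df.drop(columns=[time_col, event_col]).reset_index(drop=True)
        return cls(df[time_col].to_numpy(), df[event_col].to_numpy(), cov)

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        mask = np.asarray(mask, dtype=bool)
        cov = self.covariates.loc[mask].reset_index(drop=True) if len(self.covariates) else self.covariates
        return SurvivalDataset(self.time[mask], self.event[mask], cov)


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier product-limit estimate as a right-continuous step
    function: S(t) jumps only at event times; S(0) = 1."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def prob_at(self, t: float) -> float:
        """S(t): the post-jump value at event times (right-continuity)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        idx = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(d: SurvivalDataset) -> KMCurve:
    """Product-limit estimator; at tied times events precede censorings."""
    kmf = KaplanMeierFitter()
    kmf.fit(d.time, event_observed=d.event)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()[mask]
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int)[mask],
        n_events=table["observed"].to_numpy(dtype=int)[mask],
    )


def km_prob_at(curve: KMCurve, t: float) -> float:
    """Survival probability at time ``t`` read off the KM step function."""
    return curve.prob_at(t)


def logrank_test(groups: Sequence[SurvivalDataset]) -> TestResult:
    """Unweighted k-group log-rank test.

    At each distinct event time the observed events per group are compared
    with their hypergeometric expectation given the at-risk counts; the
    chi-square statistic has k-1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    time = np.concatenate([g.time for g in groups])
    event = np.concatenate([g.event for g in groups])
    label = np.concatenate([np.full(len(g), j) for j, g in enumerate(groups)])
    if event.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")

    event_times = np.unique(time[event == 1])
    # at-risk count per group at each event time, via sorted suffix counts
    n_mat = np.empty((event_times.size, k))
    d_mat = np.zeros((event_times.size, k))
    for j in range(k):
        tj = np.sort(time[label == j])
        n_mat[:, j] = tj.size - np.searchsorted(tj, event_times, side="left")
        tj_events = time[(label == j) & (event == 1)]
        idx = np.searchsorted(event_times, tj_events)
        np.add.at(d_mat[:, j], idx, 1.0)
    n_tot = n_mat.sum(axis=1)
    d_tot = d_mat.sum(axis=1)
    o_minus_e = (d_mat - d_tot[:, None] * n_mat / n_tot[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1.0), 0.0)
    diag_part = np.einsum("u,uj->j", factor / n_tot, n_mat)
    cov = np.diag(diag_part) - np.einsum("u,uj,ul->jl", factor / n_tot**2, n_mat, n_mat)

    z = o_minus_e[:-1]
    v = cov[:-1, :-1]
    statistic = float(z @ np.linalg.pinv(v) @ z)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(statistic=statistic, df=df, p_value=p, method="log-rank")


def logrank_from_mask(d: SurvivalDataset, mask: np.ndarray) -> TestResult:
    """Two-group log-rank for a boolean partition of one dataset."""
    mask = np.asarray(mask, dtype=bool)
    return logrank_test([d.subset(mask), d.subset(~mask)])


def km_table(curves: dict[str, KMCurve]) -> pd.DataFrame:
    """Long-format table of labelled KM curves (for km_curves.csv)."""
    frames = []
    for label, c in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": c.event_times,
                    "survival": c.survival,
                    "at_risk": c.at_risk,
                    "n_events": c.n_events,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group", "time", "survival", "at_risk", "n_events"]
    )
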