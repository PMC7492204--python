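"""Group-comparison statistics for baseline characteristics.

The study's baseline table compares the mono- and polysymptomatic index
relapse groups with a pooled two-sample t-test for ages, a Pearson chi-square
(no continuity correction) for categorical factors, and Wilcoxon rank-sum or
Mood's median test for skewed continuous measures.  The t-test is also
available directly from printed summary statistics (mean, SD, n), which is
how the published values can be recomputed without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import TestResult


@dataclass(frozen=True)
class SummaryStats:
    """Mean, standard deviation and sample size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStats":
        x = np.asarray(values, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or np.any(counts < 0) or counts.sum() == 0:
            raise ValueError("counts must be a non-negative 2-D table with positive total")


def ttest_from_summary(a: SummaryStats, b: SummaryStats, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test from summary statistics.

    Pooled-variance by default (df = n_a + n_b - 2); ``welch=True`` uses the
    Satterthwaite approximation instead.
    """
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        return TestResult(statistic=0.0, df=a.n + b.n - 2, p_value=1.0, method="t-pooled")
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        t = (a.mean - b.mean) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = "t-welch"
    else:
        df = a.n + b.n - 2
        if df < 1:
            raise ValueError("pooled t-test needs n_a + n_b - 2 >= 1")
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        method = "t-pooled"
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=int(round(df)), p_value=float(p), method=method)


def ttest_raw(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TestResult:
    """Two-sample t on raw values; identical to the summary-statistic form."""
    return ttest_from_summary(SummaryStats.from_values(x), SummaryStats.from_values(y), welch)


def pearson_chi2(t: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = np.asarray(t.counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    statistic, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(statistic), df=int(df), p_value=float(p), method="pearson-chi2")


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float], exact_below: int = 15) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Midranks for ties with the tie-corrected normal approximation; below
    ``exact_below`` observations per group (and without ties) the exact null
    distribution is enumerated instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) < exact_below and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return TestResult(
        statistic=float(res.statistic),
        df=1,
        p_value=float(res.pvalue),
        method=f"wilcoxon-ranksum-{method}",
    )


def mood_median_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mood's median test: chi-square on counts above vs <= the pooled median."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate pooled median: all values equal")
    statistic, p, _, table = stats.median_test(x, y, ties="below", correction=False)
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate pooled median: one side of the median is empty")
    return TestResult(statistic=float(statistic), df=1, p_value=float(p), method="mood-median")


# ---------------------------------------------------------------------------
# Baseline-table report

_CONTINUOUS_NORMAL = [("age_at_baseline", "Age at baseline, yrs"),
                      ("age_at_first_symptom", "Age at first MS symptom, yrs")]
_CONTINUOUS_SKEWED = [("disease_duration", "Disease duration, yrs", "wilcoxon"),
                      ("baseline_edss", "EDSS", "median"),
                      ("relapse_count_2y", "Number of relapses 2 yrs prior to baseline", "median"),
                      ("dmt_duration", "Duration of DMT, yrs", "wilcoxon")]
_CATEGORICAL = [("sex", "Sex"),
                ("dominant_symptom", "Dominant symptom of the index relapse"),
                ("most_affected_kfs", "Most disabled KFS"),
                ("prior_dmt", "DMT prior to baseline")]

_METHOD_FOOTNOTES = {"t-pooled": "a", "pearson-chi2": "b",
                     "wilcoxon-ranksum-asymptotic": "c", "wilcoxon-ranksum-exact": "c",
                     "mood-median": "d"}


def table1_report(patients: pd.DataFrame, group_col: str = "index_phenotype") -> pd.DataFrame:
    """Baseline-characteristics comparison of the two phenotype groups.

    One row per characteristic: group summaries, the p-value, and a method
    footnote (a = pooled t, b = Pearson chi-square, c = Wilcoxon rank-sum,
    d = median test).
    """
    groups = sorted(patients[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    ga = patients[patients[group_col] == groups[0]]
    gb = patients[patients[group_col] == groups[1]]

    rows = []

    def _fmt_mean(s: pd.Series) -> str:
        return f"{s.mean():.1f} +/- {s.std(ddof=1):.1f}"

    def _fmt_median(s: pd.Series) -> str:
        return f"{s.median():g} ({s.min():g}-{s.max():g})"

    for col, label in _CONTINUOUS_NORMAL:
        res = ttest_raw(ga[col], gb[col])
        rows.append((label, _fmt_mean(ga[col]), _fmt_mean(gb[col]), res.p_value,
                     _METHOD_FOOTNOTES[res.method]))
    for col, label, which in _CONTINUOUS_SKEWED:
        res = (wilcoxon_ranksum if which == "wilcoxon" else mood_median_test)(
            ga[col].to_numpy(), gb[col].to_numpy()
        )
        rows.append((label, _fmt_median(ga[col]), _fmt_median(gb[col]), res.p_value,
                     _METHOD_FOOTNOTES[res.method]))
    for col, label in _CATEGORICAL:
        levels = sorted(patients[col].unique())
        counts = np.array([[int((g[col] == lv).sum()) for lv in levels] for g in (ga, gb)])
        res = pearson_chi2(ContingencyTable(counts, tuple(groups), tuple(map(str, levels))))
        summ = [
            "; ".join(f"{lv}: {int((g[col] == lv).sum())}" for lv in levels)
            for g in (ga, gb)
        ]
        rows.append((label, summ[0], summ[1], res.p_value, _METHOD_FOOTNOTES[res.method]))

    return pd.DataFrame(
        rows, columns=["characteristic", groups[0], groups[1], "p_value", "method"]
    )
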