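"""Cox proportional-hazards regression by partial-likelihood Newton iteration.

Written in-package because the CART split search needs the partial-likelihood
score test at beta = 0 (in both Efron and Breslow tie modes), which is the
quantity whose Breslow form coincides with the two-group log-rank statistic
for a binary covariate without ties — the identity the test suite exploits as
a cross-operation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import SurvivalDataset, TestResult

Z_95 = 1.959964  # two-sided 95% normal quantile


class DegenerateCovariateError(ValueError):
    """A requested covariate is constant (no partial-likelihood information)."""


def _partial_likelihood_terms(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score vector and information matrix at beta.

    Processes distinct times in descending order so the risk-set sums
    S0 = sum exp(eta), S1 = sum x exp(eta), S2 = sum x x' exp(eta) are plain
    running totals; Efron's correction removes the tied-event mass in equal
    fractions l/m, Breslow's removes none.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # rescale for overflow safety; cancels in every ratio
    w = np.exp(eta)

    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        block = order[i:j]  # all subjects entering the risk set at this time
        wb = w[block]
        Xb = X[block]
        S0 += wb.sum()
        S1 += Xb.T @ wb
        S2 += (Xb * wb[:, None]).T @ Xb

        deaths = block[event[block] == 1]
        m = deaths.size
        if m:
            wd = w[deaths]
            Xd = X[deaths]
            s0d = wd.sum()
            s1d = Xd.T @ wd
            s2d = (Xd * wd[:, None]).T @ Xd
            ll += float(eta[deaths].sum())
            score += Xd.sum(axis=0)
            for l in range(m):
                c = l / m if ties == "efron" else 0.0
                d0 = S0 - c * s0d
                d1 = S1 - c * s1d
                d2 = S2 - c * s2d
                ll -= np.log(d0)
                score -= d1 / d0
                info += d2 / d0 - np.outer(d1, d1) / d0**2
        i = j
    return ll, score, info


def _score_terms_null_1d(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, ties: str
) -> tuple[float, float]:
    """Score U and information I of a single covariate at beta = 0.

    Vectorized: at beta = 0 the risk-set sums are plain suffix counts, so the
    whole computation reduces to sorted cumulative sums plus a flattened
    Efron adjustment over tied events.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    xs = x[order].astype(float)

    # suffix sums over the risk set {j : t_j >= u}
    s0_suffix = np.arange(len(t), 0, -1, dtype=float)
    s1_suffix = np.cumsum(xs[::-1])[::-1]
    s2_suffix = np.cumsum((xs**2)[::-1])[::-1]

    te = t[e]
    xe = xs[e]
    uniq, start_in_e, counts = np.unique(te, return_index=True, return_counts=True)
    first_idx = np.searchsorted(t, uniq, side="left")
    S0 = s0_suffix[first_idx]
    S1 = s1_suffix[first_idx]
    S2 = s2_suffix[first_idx]
    csum = np.concatenate([[0.0], np.cumsum(xe)])
    csum2 = np.concatenate([[0.0], np.cumsum(xe**2)])
    s1d = csum[start_in_e + counts] - csum[start_in_e]
    s2d = csum2[start_in_e + counts] - csum2[start_in_e]
    d = counts.astype(float)

    if ties == "breslow":
        U = float(s1d.sum() - (d * S1 / S0).sum())
        I = float((d * (S2 / S0 - (S1 / S0) ** 2)).sum())
        return U, I

    # Efron: expand l = 0..d_k-1 per tied-event group
    total = int(d.sum())
    offsets = np.repeat(np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
    l = np.arange(total) - offsets
    c = l / np.repeat(d, counts)
    S0r = np.repeat(S0, counts) - c * np.repeat(d, counts)
    S1r = np.repeat(S1, counts) - c * np.repeat(s1d, counts)
    S2r = np.repeat(S2, counts) - c * np.repeat(s2d, counts)
    U = float(s1d.sum() - (S1r / S0r).sum())
    I = float((S2r / S0r - (S1r / S0r) ** 2).sum())
    return U, I


def score_test_1d(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, ties: str = "efron"
) -> TestResult:
    """Fast single-covariate Cox score test at coefficient zero."""
    U, I = _score_terms_null_1d(
        np.asarray(time, float), np.asarray(event, int), np.asarray(x, float), ties
    )
    statistic = U * U / I if I > 0 else 0.0
    return TestResult(
        statistic=float(statistic),
        df=1,
        p_value=float(stats.chi2.sf(statistic, 1)),
        method=f"cox-score-{ties}",
    )


@dataclass
class CoxPHResults:
    """Fitted hazard-ratio inference for a Cox proportional-hazards model."""

    params: pd.Series  # log hazard ratios
    bse: pd.Series
    hr: pd.Series
    ci95_low: pd.Series
    ci95_high: pd.Series
    wald_p: pd.Series
    score_statistic: float
    score_p: float
    loglik: float
    converged: bool
    n: int
    n_events: int
    ties: str
    n_iter: int

    def summary(self) -> pd.DataFrame:
        """Per-covariate estimates in the form study tables report them."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.bse,
                "HR": self.hr,
                "HR 95% CI low": self.ci95_low,
                "HR 95% CI high": self.ci95_high,
                "Wald p": self.wald_p,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"CoxPHResults(n={self.n}, events={self.n_events}, ties={self.ties}, "
            f"converged={self.converged}, score p={self.score_p:.3g})",
            self.summary().to_string(),
        ]
        return "\n".join(lines)


class CoxPHModel:
    """Cox proportional-hazards model on a :class:`SurvivalDataset`.

    Parameters
    ----------
    data:
        Survival rows with covariates.
    covariates:
        Names of covariate columns to include (must be numeric and
        non-constant).
    ties:
        ``"efron"`` (default, more accurate with tied event times) or
        ``"breslow"``.
    """

    def __init__(
        self,
        data: SurvivalDataset,
        covariates: Sequence[str],
        ties: str = "efron",
    ) -> None:
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        missing = [c for c in covariates if c not in data.covariates.columns]
        if missing:
            raise KeyError(f"covariates not in dataset: {missing}")
        X = data.covariates[list(covariates)].to_numpy(dtype=float)
        for idx, name in enumerate(covariates):
            if np.ptp(X[:, idx]) == 0:
                raise DegenerateCovariateError(f"covariate {name!r} is constant")
        self.data = data
        self.names = list(covariates)
        self.ties = ties
        self._X = X - X.mean(axis=0)  # centering: stabilizes, leaves beta unchanged

    def score_test(self, ties: Optional[str] = None) -> TestResult:
        """Partial-likelihood score test of all coefficients = 0."""
        mode = ties or self.ties
        if self._X.shape[1] == 1:
            return score_test_1d(self.data.time, self.data.event, self._X[:, 0], mode)
        _, score, info = _partial_likelihood_terms(
            self.data.time, self.data.event, self._X, np.zeros(len(self.names)), mode
        )
        statistic = float(score @ np.linalg.pinv(info) @ score)
        df = len(self.names)
        return TestResult(
            statistic=statistic,
            df=df,
            p_value=float(stats.chi2.sf(statistic, df)),
            method=f"cox-score-{mode}",
        )

    def fit(self, max_iter: int = 50, tol: float = 1e-10) -> CoxPHResults:
        """Maximize the partial likelihood by damped Newton iteration."""
        time, event, X = self.data.time, self.data.event, self._X
        p = X.shape[1]
        beta = np.zeros(p)
        ll, score, info = _partial_likelihood_terms(time, event, X, beta, self.ties)
        score0, info0 = score.copy(), info.copy()  # beta=0 quantities for the score test
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.pinv(info) @ score
            new_beta = beta + step
            new_ll, new_score, new_info = _partial_likelihood_terms(
                time, event, X, new_beta, self.ties
            )
            halvings = 0
            while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
                step *= 0.5
                new_beta = beta + step
                new_ll, new_score, new_info = _partial_likelihood_terms(
                    time, event, X, new_beta, self.ties
                )
                halvings += 1
            delta_ll = abs(new_ll - ll)
            beta, ll, score, info = new_beta, new_ll, new_score, new_info
            if delta_ll < tol and np.linalg.norm(score) < 1e-6:
                converged = True
                break

        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        wald_p = 2 * stats.norm.sf(np.abs(z))
        score_stat = float(score0 @ np.linalg.pinv(info0) @ score0)
        idx = pd.Index(self.names, name="covariate")
        return CoxPHResults(
            params=pd.Series(beta, index=idx),
            bse=pd.Series(se, index=idx),
            hr=pd.Series(np.exp(beta), index=idx),
            ci95_low=pd.Series(np.exp(beta - Z_95 * se), index=idx),
            ci95_high=pd.Series(np.exp(beta + Z_95 * se), index=idx),
            wald_p=pd.Series(wald_p, index=idx),
            score_statistic=score_stat,
            score_p=float(stats.chi2.sf(score_stat, p)),
            loglik=float(ll),
            converged=converged,
            n=len(self.data),
            n_events=self.data.n_events,
            ties=self.ties,
            n_iter=it,
        )


def cox_fit(
    d: SurvivalDataset, covariate_names: Sequence[str], ties: str = "efron"
) -> CoxPHResults:
    """Fit a Cox model; convenience wrapper over :class:`CoxPHModel`."""
    return CoxPHModel(d, covariate_names, ties=ties).fit()


def cox_score_test(
    d: SurvivalDataset, covariate_names: Sequence[str], ties: str = "efron"
) -> TestResult:
    """Score test of the named covariates at coefficient zero."""
    return CoxPHModel(d, covariate_names, ties=ties).score_test()
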