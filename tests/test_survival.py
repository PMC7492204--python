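"""Kaplan-Meier, log-rank, Cox partial likelihood, and cut-point search."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from cdaf.coxph import CoxPHModel, DegenerateCovariateError, cox_fit, cox_score_test
from cdaf.cutpoints import best_binary_split
from cdaf.survival import (
    KMCurve,
    SurvivalDataset,
    km_estimate,
    km_prob_at,
    logrank_test,
)


def dataset(times, events, **covs):
    cov = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in covs.items()})
    return SurvivalDataset(np.asarray(times, float), np.asarray(events, int), cov)


def random_dataset(rng, n, tie_rounding=None, with_censoring=True):
    t = rng.exponential(10.0, n)
    if tie_rounding is not None:
        t = np.round(t, tie_rounding)
    t = np.maximum(t, 0.01)
    e = rng.integers(0, 2, n) if with_censoring else np.ones(n, int)
    x = rng.integers(0, 2, n)
    return t, e, x


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # {2 event, 4 censored, 6 event}: S(2)=2/3, S(6)=0
        curve = km_estimate(dataset([2, 4, 6], [1, 0, 1]))
        assert np.allclose(curve.event_times, [2, 6])
        assert np.allclose(curve.survival, [2 / 3, 0.0])

    def test_step_function_lookup(self):
        curve = km_estimate(dataset([2, 4, 6], [1, 0, 1]))
        assert km_prob_at(curve, 0) == 1.0
        assert km_prob_at(curve, 1.9) == 1.0
        assert km_prob_at(curve, 2) == pytest.approx(2 / 3)  # right-continuous
        assert km_prob_at(curve, 3) == pytest.approx(2 / 3)
        assert km_prob_at(curve, 6) == 0.0

    def test_all_censored_gives_constant_one(self):
        curve = km_estimate(dataset([1, 2, 3], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert km_prob_at(curve, 10) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(42)
        t = np.round(rng.exponential(5, 200), 2) + 0.01
        curve = km_estimate(dataset(t, np.ones_like(t)))
        for u in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km_prob_at(curve, u) == pytest.approx((t > u).mean(), abs=1e-12)

    def test_large_sample_matches_exponential(self):
        rng = np.random.default_rng(7)
        h = 0.3
        t = rng.exponential(1 / h, 10000)
        curve = km_estimate(dataset(t, np.ones_like(t)))
        grid = np.linspace(0.1, 10, 50)
        sup = max(abs(km_prob_at(curve, u) - np.exp(-h * u)) for u in grid)
        assert sup < 0.02


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        d = dataset([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test([d, d])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_label_swap_symmetry(self):
        a = dataset([1, 3, 5], [1, 1, 0])
        b = dataset([2, 4, 6], [1, 0, 1])
        assert logrank_test([a, b]).statistic == pytest.approx(
            logrank_test([b, a]).statistic
        )

    def test_hand_hypergeometric_oracle(self):
        # groups {1e,2e} vs {3e,4e}: tabulate O-E and V per event time by hand
        a = dataset([1, 2], [1, 1])
        b = dataset([3, 4], [1, 1])
        o_minus_e, v = 0.0, 0.0
        # (event time, at-risk in a, at-risk in b, observed events in a)
        risk = [(1, 2, 2, 1), (2, 1, 2, 1), (3, 0, 2, 0), (4, 0, 1, 0)]
        for _t, na, nb, oa in risk:
            n = na + nb
            o_minus_e += oa - na / n
            v += (na * nb) / n**2 if n > 1 else 0.0  # d=1 so (n-d)/(n-1)=1
        expected = o_minus_e**2 / v
        assert logrank_test([a, b]).statistic == pytest.approx(expected, rel=1e-12)

    def test_matches_lifelines_multigroup(self):
        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(8, 120), 1) + 0.1
        e = rng.integers(0, 2, 120)
        g = rng.integers(0, 3, 120)
        mine = logrank_test(
            [SurvivalDataset(t[g == j], e[g == j]) for j in range(3)]
        )
        ref = multivariate_logrank_test(t, g, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.df == 2

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(4, 60) + 0.1
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60)
        groups = lambda tt: [SurvivalDataset(tt[g == j], e[g == j]) for j in range(2)]
        s1 = logrank_test(groups(t)).statistic
        s2 = logrank_test(groups(np.exp(t / 5))).statistic
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_zero_events_raises(self):
        with pytest.raises(ValueError):
            logrank_test([dataset([1, 2], [0, 0]), dataset([3], [0])])


class TestCox:
    def test_null_effect_gives_zero_coefficient(self):
        # two balanced groups with identical event patterns
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        x = [0] * 5 + [1] * 5
        fit = cox_fit(dataset(t, e, x=x), ["x"])
        assert abs(fit.params.iloc[0]) < 1e-6

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2) * x))
        cens = np.quantile(t, 0.8)
        e = (t <= cens).astype(int)
        t = np.minimum(t, cens)
        fit = cox_fit(dataset(np.maximum(t, 1e-6), e, x=x), ["x"])
        assert 1.8 < fit.hr.iloc[0] < 2.2
        assert fit.converged

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines(self, ties):
        rng = np.random.default_rng(2)
        t, e, x = random_dataset(rng, 300, tie_rounding=1)
        z = rng.normal(size=300)
        df = pd.DataFrame({"T": t, "E": e, "x": x.astype(float), "z": z})
        mine = cox_fit(dataset(t, e, x=x, z=z), ["x", "z"], ties=ties)
        ref = CoxPHFitter().fit(df, "T", "E")  # lifelines default is Efron
        if ties == "efron":
            assert np.allclose(mine.params.to_numpy(), ref.params_.to_numpy(), atol=1e-5)
            assert np.allclose(mine.bse.to_numpy(), ref.standard_errors_.to_numpy(), atol=1e-5)

    def test_ci_contains_hr_and_is_positive(self):
        rng = np.random.default_rng(4)
        t, e, x = random_dataset(rng, 200)
        fit = cox_fit(dataset(t, e, x=x), ["x"])
        assert 0 < fit.ci95_low.iloc[0] <= fit.hr.iloc[0] <= fit.ci95_high.iloc[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            cox_fit(dataset([1, 2, 3], [1, 1, 0], x=[1, 1, 1]), ["x"])

    def test_summary_table_shape(self):
        rng = np.random.default_rng(6)
        t, e, x = random_dataset(rng, 100)
        table = cox_fit(dataset(t, e, x=x), ["x"]).summary()
        assert list(table.columns) == ["coef", "se(coef)", "HR", "HR 95% CI low", "HR 95% CI high", "Wald p"]
        assert list(table.index) == ["x"]


class TestScoreLogrankIdentity:
    def test_breslow_score_equals_logrank_without_ties(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            n = int(rng.integers(10, 41))
            t = rng.exponential(10, n)
            e = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n)
            if e.sum() == 0 or x.min() == x.max() or np.unique(t).size < n:
                continue
            d = dataset(t, e, x=x)
            score = cox_score_test(d, ["x"], ties="breslow").statistic
            lr = logrank_test([d.subset(x == 0), d.subset(x == 1)]).statistic
            assert abs(score - lr) <= 1e-8 * max(1.0, lr)
            checked += 1

    def test_with_sparse_ties_agreement_within_tolerance(self):
        # the two statistics differ only through the hypergeometric variance
        # factor (n-d)/(n-1) at tied times, so with a few tied pairs at
        # n=300 agreement holds to ~1e-3 relative
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 300
            t = rng.exponential(5, n) + 0.1
            order = np.argsort(t)
            t[order[1::2][:4]] = t[order[::2][:4]]  # tied pairs, early times
            e = np.ones(n, int)
            e[rng.choice(n, 60, replace=False)] = 0
            x = rng.integers(0, 2, n)
            d = dataset(t, e, x=x)
            score = cox_score_test(d, ["x"], ties="breslow").statistic
            lr = logrank_test([d.subset(x == 0), d.subset(x == 1)]).statistic
            assert score == pytest.approx(lr, rel=1e-3, abs=1e-6)


class TestBestBinarySplit:
    def test_relapse_count_candidate_thresholds(self):
        # counts over {1..4}: candidates are exactly 1|2-4, 1-2|3-4, 1-3|4
        rng = np.random.default_rng(0)
        n = 200
        counts = rng.integers(1, 5, n).astype(float)
        t = rng.exponential(10 / counts)
        from cdaf.cutpoints import _candidate_masks

        cands = _candidate_masks(pd.Series(counts), "ordinal")
        assert [thr for thr, _, _ in cands] == [1.0, 2.0, 3.0]

    def test_constant_variable_yields_no_split(self):
        d = dataset([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [1] * 10, x=[2.0] * 10)
        assert best_binary_split(d, "x", "ordinal") is None

    def test_min_size_respected(self):
        rng = np.random.default_rng(1)
        t, e, _ = random_dataset(rng, 30)
        x = np.array([0.0] * 3 + [1.0] * 27)  # left side would have 3 < 5
        d = dataset(t, np.maximum(e, 1), x=x)
        assert best_binary_split(d, "x", "binary", min_size=5) is None

    def test_planted_changepoint_recovered(self):
        # hazard doubles above the known decile threshold
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.normal(size=n)
            thr = np.quantile(x, 0.6)
            rate = np.where(x > thr, 2.0, 1.0)
            t = rng.exponential(1.0 / rate)
            d = dataset(np.maximum(t, 1e-6), np.ones(n, int), x=x)
            split = best_binary_split(d, "x", "continuous")
            assert split is not None
            # the selected decile threshold should be the planted 60% decile
            hits += abs(split.threshold - thr) < 1e-9
        assert hits >= 16  # >= 80% of seeds

    def test_categorical_one_vs_rest(self):
        rng = np.random.default_rng(8)
        n = 300
        levels = rng.choice(["a", "b", "c"], n)
        rate = np.where(levels == "b", 3.0, 1.0)
        t = rng.exponential(1.0 / rate)
        d = dataset(np.maximum(t, 1e-6), np.ones(n, int), g=np.zeros(n))
        d.covariates["g"] = levels
        split = best_binary_split(d, "g", "categorical")
        assert split.left_levels == frozenset(["b"])
        assert split.score_p < 0.001 and split.logrank_p < 0.001
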