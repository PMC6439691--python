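"""Kaplan-Meier, log-rank, Cox regression and group comparisons.

Cross-checks use lifelines as an independent oracle; closed-form oracles
are computed inline.
"""

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from chipcall.survival import (
    SeparationError,
    cox_ph,
    group_compare,
    km_estimate,
    logrank_test,
    nt_probnp_per_1000,
    pearson_r,
    stepwise_cox,
    tertile_indicators,
)
import pandas as pd


def censored_sample(n=120, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.exponential(4.0, n)
    c = rng.exponential(6.0, n)
    times = np.minimum(t, c)
    events = t <= c
    return times, events


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert list(km.n_at_risk) == [3, 2, 1]

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert km.times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_single_event_among_four(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [True, False, False, False])
        assert km.survival_at(1.0) == pytest.approx(0.75)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2.0, 50)
        km = km_estimate(t, np.ones(50, bool))
        for q in [0.5, 1.0, 2.0, 4.0]:
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines_with_censoring(self):
        times, events = censored_sample(seed=7)
        km = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        assert np.allclose(km.survival, theirs)

    def test_greenwood_variance_hand_example(self):
        # times 1,2 events among n=4 with censoring at 1.5
        km = km_estimate([1.0, 1.5, 2.0, 3.0], [True, False, True, False])
        # step 1: S=3/4, var = S^2 * (1/(4*3))
        assert km.greenwood_var[0] == pytest.approx((3 / 4) ** 2 * (1 / 12))
        # step 2: n=2, d=1, S=3/8
        s2 = (3 / 4) * (1 / 2)
        assert km.greenwood_var[1] == pytest.approx(s2**2 * (1 / 12 + 1 / 2))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [True] * 6
        groups = [0, 0, 0, 1, 1, 1]
        res = logrank_test(groups, times, events)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_single_event_closed_form(self):
        # one event in group 0 at t=1 with 2 at risk in each group:
        # O-E = 1 - 2/4 = 0.5, V = 1*(4-1)/(4-1) * (2/4)(1-2/4) = 0.25
        groups = [0, 0, 1, 1]
        times = [1.0, 5.0, 4.0, 6.0]
        events = [True, False, False, False]
        res = logrank_test(groups, times, events)
        assert res.statistic == pytest.approx(0.5**2 / 0.25)

    def test_label_swap_invariant(self):
        times, events = censored_sample(seed=11)
        groups = (np.arange(times.size) % 2).astype(int)
        a = logrank_test(groups, times, events)
        b = logrank_test(1 - groups, times, events)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_lifelines_three_groups(self):
        times, events = censored_sample(n=150, seed=13)
        groups = np.arange(150) % 3
        res = logrank_test(groups, times, events)
        theirs = multivariate_logrank_test(times, groups, events)
        assert res.statistic == pytest.approx(theirs.test_statistic, rel=1e-8)
        assert res.p_value == pytest.approx(theirs.p_value, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([0, 0], [1.0, 2.0], [True, True])


class TestCox:
    def test_symmetric_groups_give_null_coefficient(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [True, True, False, True, True, False]
        x = np.array([0, 0, 0, 1, 1, 1], float)
        res = cox_ph(x, times, events)
        assert res.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert res.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(17)
        n = 80
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        t += rng.uniform(0, 1e-6, n)  # break accidental ties
        e = rng.random(n) < 0.7
        efron = cox_ph(x, t, e, ties="efron")
        breslow = cox_ph(x, t, e, ties="breslow")
        assert np.allclose(efron.coef, breslow.coef, atol=1e-8)
        assert efron.loglik == pytest.approx(breslow.loglik)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(19)
        n = 150
        x = rng.normal(size=(n, 2))
        t = np.ceil(rng.exponential(np.exp(-0.6 * x[:, 0] + 0.3 * x[:, 1])) * 4) / 4
        e = rng.random(n) < 0.75
        mine = cox_ph(x, t, e, names=["a", "b"])
        df = pd.DataFrame({"t": t, "e": e, "a": x[:, 0], "b": x[:, 1]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.allclose(mine.coef, cph.params_[["a", "b"]].to_numpy(), atol=1e-5)
        assert np.allclose(mine.se, cph.standard_errors_[["a", "b"]].to_numpy(), atol=1e-5)

    def test_ci_brackets_hazard_ratio(self):
        times, events = censored_sample(seed=23)
        x = (np.arange(times.size) % 2).astype(float)
        res = cox_ph(x, times, events)
        assert res.ci_low[0] < res.hr[0] < res.ci_high[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph(np.ones(10), np.arange(1, 11.0), np.ones(10, bool))

    def test_complete_separation_detected(self):
        # all early events in one group, all late censorings in the other
        x = np.r_[np.ones(10), np.zeros(10)]
        t = np.r_[np.linspace(0.1, 1, 10), np.full(10, 50.0)]
        e = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        with pytest.raises(SeparationError):
            cox_ph(x, t, e)


class TestStepwise:
    def test_tertile_encoding_splits_evenly(self):
        ind = tertile_indicators(np.arange(1.0, 10.0))
        assert ind["tertile_2"].sum() == 3
        assert ind["tertile_3"].sum() == 3

    def test_nt_probnp_rescaling(self):
        assert np.allclose(nt_probnp_per_1000([500, 2500]), [0.5, 2.5])

    def test_strong_candidate_retained_null_excluded(self):
        rng = np.random.default_rng(31)
        n = 300
        strong = rng.normal(size=n)
        null = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.9 * strong))
        e = rng.random(n) < 0.8
        res = stepwise_cox(
            base=pd.DataFrame(index=range(n)),
            candidates=pd.DataFrame({"strong": strong, "null": null}),
            times=t,
            events=e,
        )
        assert res.entered == ["strong"]
        assert res.log[0]["entered"] == "strong"


class TestGroupCompare:
    def test_chi_square_matches_textbook_formula(self):
        # 2x2 carrier/non-carrier hypertension table
        a, b, c, d = 36, 2, 123, 39
        n = a + b + c + d
        expected_stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        values = np.array([1] * (a + c) + [0] * (b + d))
        groups = np.array(["chip"] * a + ["non"] * c + ["chip"] * b + ["non"] * d)
        res = group_compare(values, groups, "categorical")
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(expected_stat)

    def test_identical_distributions_give_p_near_one(self):
        values = np.array([0, 1] * 40)
        groups = np.array(["a"] * 40 + ["b"] * 40)
        res = group_compare(values, groups, "categorical")
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # table [[1, 9], [11, 3]]
        table = np.array([[1, 9], [11, 3]])
        values = np.array([0] * 10 + [1] * 14)
        groups = np.r_[["g1"] * 1, ["g2"] * 9, ["g1"] * 11, ["g2"] * 3]
        res = group_compare(values, groups, "categorical")
        assert res.test == "fisher"
        # enumeration oracle: sum P(tables as or more extreme) under fixed margins
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        probs = [stats.hypergeom.pmf(k, n, r1, c1) for k in range(max(0, c1 - r2), min(r1, c1) + 1)]
        p_obs = stats.hypergeom.pmf(table[0, 0], n, r1, c1)
        p_exact = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_anova_for_continuous(self):
        rng = np.random.default_rng(31)
        values = np.r_[rng.normal(0, 1, 40), rng.normal(2, 1, 40)]
        groups = np.r_[["a"] * 40, ["b"] * 40]
        res = group_compare(values, groups, "continuous")
        assert res.test == "anova"
        assert res.p_value < 0.001


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)
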