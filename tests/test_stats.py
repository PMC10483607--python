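"""Statistical machinery against independent oracles: sign-pattern and rank
enumeration, hypergeometric sums, hand-computed product-limit tables, and
lifelines as an external cross-check for survival."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import rankdata

from ctdnamon.stats import (
    KMCurve,
    SurvivalRecord,
    TestResult,
    contingency_test,
    gbw_test,
    km_estimate,
    mean_comparison,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def signed_rank_enumeration(diffs, two_sided=True):
    """Exact signed-rank p by enumerating all 2^m sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    m = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=m):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    mean_w = m * (m + 1) / 4
    if two_sided:
        p = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    else:
        p = np.mean(w_all >= w_obs - 1e-12)
    return float(p)


def rank_sum_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:n].sum()
    mean_w = n * (len(pooled) + 1) / 2
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    stats = np.array(stats)
    return float(np.mean(np.abs(stats - mean_w) >= abs(w_obs - mean_w) - 1e-12))


def hypergeom_2x2_enumeration(table):
    """Fisher two-sided p by direct hypergeometric summation."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (
            comb(r1, k, exact=True)
            * comb(r2, c1 - k, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = prob(a)
    return float(
        sum(prob(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1) if prob(k) <= p_obs * (1 + 1e-9))
    )


# ---------------------------------------------------------------------------


class TestSignedRank:
    def test_all_positive_n5_matches_enumeration(self):
        diffs = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert signed_rank_enumeration(diffs, two_sided=False) == pytest.approx(1 / 32)
        res = wilcoxon_signed_rank(diffs)
        assert res.exact
        assert res.p_value == pytest.approx(signed_rank_enumeration(diffs), rel=1e-12)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and "zero" in res.note

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.normal(0.3, 1.0, size=9)
        res = wilcoxon_signed_rank(diffs)
        assert res.exact
        assert res.p_value == pytest.approx(signed_rank_enumeration(diffs), rel=1e-9)

    def test_tied_large_sample_uses_approximation(self):
        rng = np.random.default_rng(3)
        diffs = np.round(rng.normal(0.2, 1.0, size=60), 1)  # forces ties
        res = wilcoxon_signed_rank(diffs)
        assert not res.exact
        assert 0.0 <= res.p_value <= 1.0

    def test_exact_and_approx_agree_at_handover(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.1, 1.0, size=25)
        exact = wilcoxon_signed_rank(diffs)
        approx = wilcoxon_signed_rank(np.concatenate([diffs, [1e-9]]))  # forces m=26
        assert abs(exact.p_value - approx.p_value) <= 0.01


class TestRankSum:
    def test_extreme_ranking_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert rank_sum_enumeration(x, y) == pytest.approx(2 / 20)
        res = wilcoxon_rank_sum(x, y)
        assert res.exact and res.p_value == pytest.approx(0.1, rel=1e-12)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=5)
        y = rng.normal(0.8, 1, size=6)
        res = wilcoxon_rank_sum(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(rank_sum_enumeration(x, y), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_power_exceeds_size_under_shift(self):
        rng = np.random.default_rng(7)
        reject_null = reject_shift = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(0, 1, 50)
            reject_null += wilcoxon_rank_sum(x, rng.normal(0, 1, 50)).p_value < 0.05
            reject_shift += wilcoxon_rank_sum(x, rng.normal(0.5, 1, 50)).p_value < 0.05
        assert reject_shift / reps > reject_null / reps
        assert reject_shift / reps > 0.5


class TestMeanComparison:
    def test_identical_groups(self):
        res = mean_comparison([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_pooled_t_matches_closed_form(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = mean_comparison([x, y])
        sp2 = (np.var(x, ddof=1) * 2 + np.var(y, ddof=1) * 2) / 4
        t_hand = (np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.statistic == pytest.approx(t_hand)
        assert res.method == "t-test" and res.df == 4

    def test_three_groups_use_anova(self):
        res = mean_comparison([[1.0, 2.0], [1.5, 2.5], [1.2, 2.2]])
        assert res.method == "anova"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mean_comparison([[1.0], [1.0, 2.0]])

    def test_anova_type_one_error(self):
        # 3 equal-mean groups: rejection rate at alpha 0.05 within +-2 SE
        rng = np.random.default_rng(8)
        reps = 1000
        rejections = sum(
            mean_comparison([rng.normal(0, 1, 15) for _ in range(3)]).p_value < 0.05
            for _ in range(reps)
        )
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 2 * se + 1e-12


class TestContingency:
    def test_balanced_table_chi_square_zero(self):
        res = contingency_test([[5, 5], [5, 5]])
        assert res.method == "chi-square"
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[3, 0], [0, 3]]
        res = contingency_test(table)
        assert res.method == "fisher-exact"
        assert res.p_value == pytest.approx(hypergeom_2x2_enumeration(table), rel=1e-9)
        assert res.p_value == pytest.approx(0.1, rel=1e-9)

    def test_large_expected_counts_take_chi_square_path(self):
        res = contingency_test([[20, 30], [25, 25]])
        assert res.method == "chi-square"

    def test_exact_rxc_agrees_with_fisher_on_2x2(self):
        # the r x c enumerator, run on a 2x2, must reproduce Fisher
        from ctdnamon.stats import _exact_rc_test

        for table in ([[3, 0], [0, 3]], [[2, 3], [4, 1]], [[1, 4], [3, 2]]):
            assert _exact_rc_test(np.array(table)) == pytest.approx(
                hypergeom_2x2_enumeration(table), rel=1e-9
            )

    def test_exact_rxc_on_2x3(self):
        res = contingency_test([[4, 1, 0], [0, 2, 3]])
        assert res.method == "exact-rxc"
        assert 0.0 < res.p_value <= 1.0

    def test_zero_margin_dropped(self):
        res = contingency_test([[3, 0, 4], [5, 0, 2]])
        assert "dropped" in res.note

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[0, 0], [0, 0]])


def recs(times, events, group=""):
    return [
        SurvivalRecord(f"s{i}", t, bool(e), group)
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = km_estimate(recs([5, 10, 15], [0, 0, 0]))
        assert km.survival_at(100) == 1.0

    def test_three_events_hand_product_limit(self):
        km = km_estimate(recs([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=200)
        km = km_estimate(recs(times, np.ones(200)))
        for t in (2.0, 5.0, 15.0):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_censored_at_event_time_counted_at_risk(self):
        # death and censoring at t=2: at-risk at 2 includes the censored one
        km = km_estimate(recs([1, 2, 2, 5], [1, 1, 0, 0]))
        idx = list(km.event_times).index(2.0)
        assert km.at_risk[idx] == 3

    def test_exponential_limit(self):
        rng = np.random.default_rng(10)
        lam = 0.05
        times = rng.exponential(1 / lam, size=5000)
        km = km_estimate(recs(times, np.ones(5000)))
        for t in (5.0, 15.0, 30.0):
            assert km.survival_at(t) == pytest.approx(math.exp(-lam * t), abs=0.02)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        times = rng.exponential(20, size=100)
        events = rng.uniform(size=100) < 0.7
        km = km_estimate(recs(times, events))
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in (5.0, 10.0, 25.0):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9
            )

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("x", 0.0, True)


class TestGBW:
    def test_identical_groups_statistic_zero(self):
        g = recs([1, 2, 3, 4], [1, 1, 0, 1])
        res = gbw_test({"a": g, "b": list(g)})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_table_matches_hand_computation(self):
        # groups A: deaths at 1, 2; B: deaths at 3, 4 (no censoring)
        a = recs([1, 2], [1, 1], "A")
        b = recs([3, 4], [1, 1], "B")
        # hand: at t=1 n=4, nA=2, d=1, e=0.5, v=d(n-d)/(n-1)*nA*nB/n^2=1*3/3*4/16=0.25
        # t=2: n=3, nA=1, e=1/3, v=1*2/2*1*2/9=2/9; t=3: n=2, nA=0; t=4: n=1
        u_hand = 4 * (1 - 0.5) + 3 * (1 - 1 / 3) + 2 * 0 + 1 * 0
        v_hand = 16 * 0.25 + 9 * 2 / 9 + 4 * ((2 * 0 * 2 / 4) / 1) + 0
        res = gbw_test({"A": a, "B": b})
        assert res.statistic == pytest.approx(u_hand**2 / v_hand, rel=1e-9)

    def test_matches_lifelines_wilcoxon_weighting(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(12)
        t1 = rng.exponential(10, 40)
        t2 = rng.exponential(18, 40)
        e1 = rng.uniform(size=40) < 0.8
        e2 = rng.uniform(size=40) < 0.8
        res = gbw_test({"a": recs(t1, e1), "b": recs(t2, e2)})
        ref = multivariate_logrank_test(
            np.concatenate([t1, t2]),
            np.array([0] * 40 + [1] * 40),
            np.concatenate([e1, e2]),
            weightings="wilcoxon",
        )
        assert res.statistic == pytest.approx(float(ref.test_statistic), rel=1e-6)
        assert res.p_value == pytest.approx(float(ref.p_value), rel=1e-6)

    def test_unit_weight_degenerates_to_logrank(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(13)
        t1 = rng.exponential(10, 30)
        t2 = rng.exponential(25, 30)
        res = gbw_test(
            {"a": recs(t1, np.ones(30)), "b": recs(t2, np.ones(30))},
            weight="logrank",
        )
        ref = multivariate_logrank_test(
            np.concatenate([t1, t2]),
            np.array([0] * 30 + [1] * 30),
            np.ones(60),
        )
        assert res.statistic == pytest.approx(float(ref.test_statistic), rel=1e-6)

    def test_three_group_df(self):
        rng = np.random.default_rng(14)
        groups = {
            k: recs(rng.exponential(10, 20), np.ones(20), k) for k in "abc"
        }
        res = gbw_test(groups)
        assert res.df == 2

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            gbw_test({"a": recs([1, 2], [0, 0]), "b": recs([3], [0])})

    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(15)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            t1 = rng.exponential(10, 30)
            t2 = rng.exponential(10, 30)
            res = gbw_test({"a": recs(t1, np.ones(30)), "b": recs(t2, np.ones(30))})
            rejections += res.p_value < 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 2 * se + 1e-12
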