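"""Exact and rank-based comparison statistics against independent oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from glycoferm.stats import (SurvivalRecord, auc_trapezoid, correlation,
                             fisher_exact, kruskal_wallis_dunn, logrank,
                             wilcoxon_rank_sum)


# ------------------------------------------------------------------ oracles
def oracle_fisher_p(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration (math.comb)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def oracle_wilcoxon_p(x, y):
    """Exact p by full enumeration of group labelings."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    mu = n * (len(pooled) + 1) / 2
    dev = abs(ranks[:n].sum() - mu)
    hits = sum(abs(ranks[list(i)].sum() - mu) >= dev - 1e-9
               for i in combinations(range(len(pooled)), n))
    return hits / comb(len(pooled), n)


# ------------------------------------------------------------------- Fisher
class TestFisher:
    def test_perfect_split(self):
        assert fisher_exact(10, 0, 0, 10).p_value == pytest.approx(
            2 / comb(20, 10), rel=1e-9)

    def test_balanced_table_p1(self):
        assert fisher_exact(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, 4)
            if a + b + c + d == 0:
                continue
            assert fisher_exact(a, b, c, d).p_value == pytest.approx(
                oracle_fisher_p(a, b, c, d), abs=1e-10)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, 4)
            mine = fisher_exact(a, b, c, d).p_value
            assert mine == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(1.5, 2, 3, 4)


# ----------------------------------------------------------------- Wilcoxon
class TestWilcoxon:
    def test_small_exact(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]).p_value == pytest.approx(1 / 3)

    def test_identical_samples_p1(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p_value == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n, m = rng.integers(2, 7, 2)
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                oracle_wilcoxon_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            mine = wilcoxon_rank_sum(x, y).p_value
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")[1]
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_with_ties(self):
        from scipy.stats import mannwhitneyu

        x = [1.0, 2.0, 2.0, 3.0, 5.0] * 3
        y = [2.0, 4.0, 4.0, 6.0, 7.0] * 3
        mine = wilcoxon_rank_sum(x, y)
        assert mine.method == "wilcoxon_rank_sum_normal"
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1]
        assert mine.p_value == pytest.approx(ref, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ----------------------------------------------------------- Kruskal-Wallis
class TestKruskalWallis:
    def test_identical_groups_h0(self):
        res = kruskal_wallis_dunn([[1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_three_groups(self):
        # groups (1,2), (3,4), (5,6): ranks sums 3, 7, 11; no ties
        # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 4.571428...
        res = kruskal_wallis_dunn([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(12 / 42 * (9 + 49 + 121) / 2 - 21)

    def test_matches_scipy(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(4)
        groups = [rng.normal(size=7), rng.normal(0.5, 1, 9), rng.normal(size=6)]
        res = kruskal_wallis_dunn(groups)
        ref_h, ref_p = kruskal(*groups)
        assert res.statistic == pytest.approx(ref_h, abs=1e-10)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_two_groups_consistent_with_wilcoxon(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = rng.normal(0.8, 1, 15)
        kw = kruskal_wallis_dunn([x, y]).p_value
        # compare against the tie-free normal approximation (no continuity
        # correction in KW), agreement within 0.01
        wrs = wilcoxon_rank_sum(x, y, exact_limit=0).p_value
        assert kw == pytest.approx(wrs, abs=0.01)

    def test_dunn_pairwise_holm_monotone(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=8), rng.normal(2, 1, 8), rng.normal(4, 1, 8)]
        res = kruskal_wallis_dunn(groups)
        dunn = res.extra["dunn"]
        assert len(dunn) == 3
        assert (dunn["p_adj"] >= dunn["p_raw"] - 1e-15).all()


# ----------------------------------------------------------------- log-rank
class TestLogrank:
    def test_identical_experiences_p1(self):
        recs = [SurvivalRecord(f"{g}{i}", g, t, True)
                for g in ("a", "b") for i, t in enumerate([2.0, 5.0, 9.0])]
        res = logrank(recs)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_table(self):
        # group a dies at 1, 2, 3; group b all censored at 10
        # t=1: n=6, n_a=3, d=1 -> E=0.5, V=0.25
        # t=2: n=5, n_a=2, d=1 -> E=0.4, V=0.24
        # t=3: n=4, n_a=1, d=1 -> E=0.25, V=0.1875
        recs = [SurvivalRecord(f"a{i}", "a", float(i + 1), True) for i in range(3)]
        recs += [SurvivalRecord(f"b{i}", "b", 10.0, False) for i in range(3)]
        res = logrank(recs)
        o_minus_e = 3 - (0.5 + 0.4 + 0.25)
        v = 0.25 + 0.24 + 0.1875
        assert res.statistic == pytest.approx(o_minus_e**2 / v, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(7)
        t1 = np.minimum(rng.exponential(8, 15), 14.0)
        t2 = np.minimum(rng.exponential(4, 15), 14.0)
        e1, e2 = t1 < 14, t2 < 14
        recs = [SurvivalRecord(f"a{i}", "a", t1[i], bool(e1[i])) for i in range(15)]
        recs += [SurvivalRecord(f"b{i}", "b", t2[i], bool(e2[i])) for i in range(15)]
        res = logrank(recs)
        ref = logrank_test(t1, t2, e1, e2)
        assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_no_events_rejected(self):
        recs = [SurvivalRecord("a1", "a", 5.0, False),
                SurvivalRecord("b1", "b", 5.0, False)]
        with pytest.raises(ValueError, match="events"):
            logrank(recs)


# ---------------------------------------------------------------- AUC, corr
class TestAucCorrelation:
    def test_auc_constant_and_linear(self):
        days = np.arange(0.0, 15.0)
        assert auc_trapezoid(days, np.full(15, 100.0)) == pytest.approx(1400.0)
        t = np.linspace(0, 10, 11)
        assert auc_trapezoid(t, t) == pytest.approx(50.0)

    def test_auc_matches_refined_grid(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 10, 12))
        y = rng.normal(size=12)
        fine = np.linspace(t[0], t[-1], 20001)
        oracle = np.trapezoid(np.interp(fine, t, y), fine)
        assert auc_trapezoid(t, y) == pytest.approx(oracle, abs=1e-6)

    def test_unordered_time_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])

    def test_correlation_identities(self):
        x = np.arange(10.0)
        assert correlation(x, 2 * x) == pytest.approx(1.0)
        assert correlation(x, np.exp(x / 3), method="spearman") == pytest.approx(1.0)

    def test_correlation_matches_scipy(self):
        from scipy.stats import pearsonr, spearmanr

        rng = np.random.default_rng(9)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert correlation(x, y) == pytest.approx(pearsonr(x, y)[0], abs=1e-12)
        assert correlation(x, y, method="spearman") == pytest.approx(
            spearmanr(x, y)[0], abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
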