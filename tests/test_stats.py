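"""Statistical tests against closed forms, enumeration and scipy oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from supergene.stats import (
    bonferroni,
    chi2_2x2,
    density_enrichment_chi2,
    fisher_exact_2x2,
    mk_test,
    welch_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestWelch:
    def test_identical_samples_give_p_one(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p_two_sided == 1.0

    def test_closed_form_example(self):
        r = welch_t([1, 2, 3], [2, 3, 4])
        assert r.t == pytest.approx(-1.2247448, abs=1e-6)
        assert r.df == pytest.approx(4.0)
        assert r.p_two_sided == pytest.approx(0.2878641, abs=1e-6)

    def test_scale_invariance(self):
        a = welch_t([1, 2, 3], [2, 3, 4])
        b = welch_t([10, 20, 30], [20, 30, 40])
        assert a.t == pytest.approx(b.t)
        assert a.df == pytest.approx(b.df)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_degenerate_zero_variance(self):
        same = welch_t([5.0, 5.0], [5.0, 5.0])
        assert same.degenerate and same.p_two_sided == 1.0
        diff = welch_t([5.0, 5.0], [7.0, 7.0])
        assert diff.degenerate and diff.p_two_sided == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=9), rng.normal(0.5, 2.0, size=14)
        r = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue)


class TestRankSum:
    def test_extreme_arrangement_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], side="less")
        assert w == 6.0
        assert p == pytest.approx(1 / 20)

    def test_identical_multisets_two_sided(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [3.0, 1.0, 2.0], side="two-sided")
        assert p == 1.0

    def test_label_swap_mirrors_one_sided_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(1, 1, size=7)
        _, p1 = wilcoxon_rank_sum(x, y, side="less")
        _, p2 = wilcoxon_rank_sum(y, x, side="greater")
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(20)[:6].astype(float)
        y = rng.permutation(40)[:8].astype(float) + 0.5
        _, p = wilcoxon_rank_sum(x, y, side="two-sided")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_normal_approximation_large_samples(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = rng.normal(0.8, 1, size=45)
        _, p = wilcoxon_rank_sum(x, y, side="less")
        ref = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSignedRank:
    def test_all_at_center_gives_p_one(self):
        _, p = wilcoxon_signed_rank([2.0, 2.0, 2.0], center=2.0)
        assert p == 1.0

    def test_all_above_center_minimal_p(self):
        n = 8
        _, p = wilcoxon_signed_rank(np.arange(1, n + 1) + 10.0, center=0.0,
                                    side="greater")
        assert p == pytest.approx(1 / 2**n)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0.4, 1, size=12)
        _, p = wilcoxon_signed_rank(vals, center=0.0, side="two-sided")
        ref = sps.wilcoxon(vals, alternative="two-sided", mode="exact")
        assert p == pytest.approx(ref.pvalue)


class TestChi2:
    def test_mk_table_matches_published_statistic(self):
        r = chi2_2x2([[374, 417], [209, 490]], continuity=True)
        assert round(r.statistic, 1) == 46.3

    def test_balanced_table_is_null(self):
        r = chi2_2x2([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_direct_expectation_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 60, size=(2, 2)).astype(float)
        r = chi2_2x2(t, continuity=True)
        # independent oracle: expectations from margins, Yates by hand
        n = t.sum()
        stat = 0.0
        for i in range(2):
            for j in range(2):
                e = t[i].sum() * t[:, j].sum() / n
                stat += max(abs(t[i, j] - e) - 0.5, 0.0) ** 2 / e
        assert r.statistic == pytest.approx(stat, abs=1e-12)
        ref = sps.chi2_contingency(t, correction=True)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)


def _fisher_enumeration_oracle(a, b, c, d, side):
    """Full enumeration over the hypergeometric support with math.comb."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in support}
    if side == "less":
        return sum(p for k, p in probs.items() if k <= a)
    if side == "greater":
        return sum(p for k, p in probs.items() if k >= a)
    pa = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= pa * (1 + 1e-12)))


class TestFisher:
    def test_str_proportion_table_matches_published_p(self):
        assert round(fisher_exact_2x2([[14, 163], [97, 759]]), 2) == 0.23

    def test_uniform_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    @pytest.mark.parametrize("side", ["less", "greater", "two-sided"])
    def test_matches_enumeration_oracle_small_tables(self, side):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p = fisher_exact_2x2([[a, b], [c, d]], side=side)
            oracle = _fisher_enumeration_oracle(a, b, c, d, side)
            assert p == pytest.approx(oracle, abs=1e-12), (a, b, c, d, side)


class TestMKTest:
    def test_published_counts(self):
        r = mk_test(374, 417, 209, 490)
        assert round(r.statistic, 1) == 46.3
        assert r.extra["neutrality_index"] == pytest.approx(
            (209 / 490) / (374 / 417))

    def test_proportional_rows_are_neutral(self):
        r = mk_test(30, 60, 10, 20)
        assert r.statistic == pytest.approx(0.0, abs=0.1)  # Yates floor
        assert r.extra["neutrality_index"] == pytest.approx(1.0)


class TestDensityEnrichment:
    def test_exactly_proportional_counts(self):
        r = density_enrichment_chi2(10, 90, 1000, 9000)
        assert r.statistic == pytest.approx(0.0)

    def test_all_counts_in_small_region_closed_form(self):
        # all N events in a 10% region: chi2 = N*(0.9/0.1) = 9N
        r = density_enrichment_chi2(50, 0, 100, 900)
        assert r.statistic == pytest.approx(9 * 50)

    def test_matches_scipy_chisquare(self):
        r = density_enrichment_chi2(120, 480, 2000, 6000)
        ref = sps.chisquare([120, 480], f_exp=[600 * 0.25, 600 * 0.75])
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue)


def test_bonferroni_adjusts_and_caps():
    adj, reject = bonferroni([0.01, 0.2, 0.6], alpha=0.05)
    assert adj == pytest.approx([0.03, 0.6, 1.0])
    assert list(reject) == [True, False, False]
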