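"""Nonparametric battery: worked examples, oracles, and cross-checks."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from meaburst.stats import (dunns_posthoc, kruskal_wallis, mann_whitney_u,
                            pearson_chi_square)


def permutation_mwu_p(x, y):
    """Exhaustive permutation oracle for the two-sided exact Mann-Whitney p.

    Enumerates every assignment of the pooled ranks to group x and counts
    assignments at least as extreme (in either tail) as the observed U.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_tiny_exact_example(self):
        # all 6 rank assignments of {1,2} vs {3,4}: U=0 in one, doubled
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.details["method"] == "exact"

    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_exact_matches_permutation_oracle(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 8, 2)
            x = rng.normal(size=n1)
            y = rng.normal(0.5, size=n2)
            res = mann_whitney_u(x, y)
            assert res.details["method"] == "exact"
            assert res.p_value == pytest.approx(permutation_mwu_p(x, y),
                                                abs=1e-12)

    def test_asymptotic_near_monte_carlo_permutation(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.6, size=40)
        res = mann_whitney_u(x, y)
        perm = sps.permutation_test(
            (x, y), lambda a, b: sps.mannwhitneyu(a, b)[0],
            permutation_type="independent", n_resamples=4000,
            alternative="two-sided", rng=np.random.default_rng(0))
        assert res.p_value == pytest.approx(perm.pvalue, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_reconstructed_drug_response_table(self):
        res = pearson_chi_square([[0, 33, 0], [110, 74, 12]])
        assert res.statistic == pytest.approx(43.96, abs=0.005)
        assert res.df == 2
        assert res.p_value < 0.0001

    def test_identical_proportions_zero(self):
        res = pearson_chi_square([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_direct_formula(self):
        # all expected counts are 5, so chi2 = 4 * 25/5 = 20
        res = pearson_chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_permutation_invariance_and_scaling(self, rng):
        table = rng.integers(1, 30, size=(2, 3))
        base = pearson_chi_square(table).statistic
        perm = pearson_chi_square(table[:, [2, 0, 1]][[1, 0]]).statistic
        assert perm == pytest.approx(base)
        scaled = pearson_chi_square(table * 3).statistic
        assert scaled == pytest.approx(base * 3)

    def test_zero_margin_instructive_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_chi_square([[0, 5], [0, 7]])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([3, 3], [3, 3], [3, 3])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_three_pairs_hand_value(self):
        # ranks 1..6, rank sums 3/7/11: H = 12/42 * 179/2 - 21 = 32/7
        res = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert res.statistic == pytest.approx(32 / 7)
        assert res.df == 2

    def test_two_groups_monotone_in_u(self, rng):
        # for k=2, H is the square of the (untied) MW z statistic
        x = rng.normal(size=15)
        y = rng.normal(1.0, size=15)
        h = kruskal_wallis(x, y).statistic
        u = sps.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
        n1, n2 = len(x), len(y)
        z = (u.statistic - n1 * n2 / 2) / math.sqrt(
            n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z ** 2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0])
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [])


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = dunns_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        (pair,) = res
        assert pair.z_statistic == pytest.approx(0.0)
        assert pair.p_adjusted == 1.0

    def test_two_groups_no_adjustment(self, rng):
        groups = {"a": rng.normal(size=10), "b": rng.normal(1, size=10)}
        (pair,) = dunns_posthoc(groups)
        assert pair.p_adjusted == pytest.approx(pair.p_unadjusted)

    def test_adjusted_at_least_raw(self, rng):
        groups = {k: rng.normal(i * 0.3, size=8) for i, k in
                  enumerate("abcd")}
        for pair in dunns_posthoc(groups):
            assert pair.p_adjusted >= pair.p_unadjusted
            assert pair.p_adjusted <= 1.0

    def test_well_separated_groups_all_significant(self, rng):
        groups = {"lo": rng.normal(0, 0.1, 10), "mid": rng.normal(5, 0.1, 10),
                  "hi": rng.normal(10, 0.1, 10)}
        res = dunns_posthoc(groups)
        assert len(res) == 3
        assert all(p.p_adjusted < 0.05 for p in res)

    def test_tie_corrected_variance_against_direct_formula(self, rng):
        # independent recomputation of z for one pair with ties present
        a = np.round(rng.normal(size=12), 1)
        b = np.round(rng.normal(0.8, size=15), 1)
        c = np.round(rng.normal(0.4, size=9), 1)
        res = {(r.group_a, r.group_b): r
               for r in dunns_posthoc({"a": a, "b": b, "c": c},
                                      adjustment="none")}
        pooled = np.concatenate([a, b, c])
        ranks = sps.rankdata(pooled)
        n = pooled.size
        _, t = np.unique(pooled, return_counts=True)
        var = (n * (n + 1) / 12 - (t ** 3 - t).sum() / (12 * (n - 1)))
        z = (ranks[:12].mean() - ranks[12:27].mean()) / math.sqrt(
            var * (1 / 12 + 1 / 15))
        assert res[("a", "b")].z_statistic == pytest.approx(z)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunns_posthoc({"a": [1.0], "b": []})
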