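"""Statistical primitives against independent oracles.

Each test either enumerates the null support with code independent of
the implementation, or cross-checks against scipy / statsmodels.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings, strategies as st

from mirsmoke import stats


def brute_force_permutation_p(x, y):
    """Enumerate every label assignment of the pooled sample."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    t_obs = abs(np.mean(x) - np.mean(y))
    hits = total = 0
    for idx in itertools.combinations(range(n), nx):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        t = abs(pooled[sel].mean() - pooled[~sel].mean())
        hits += t >= t_obs - 1e-12
        total += 1
    return hits / total


class TestPermutationTest:
    def test_constant_data_p_one(self):
        assert stats.permutation_test([2, 2, 2], [2, 2, 2]).p_value == 1.0

    def test_exact_enumeration_separated_groups(self):
        res = stats.permutation_test([5, 6, 7, 8], [1, 2, 3, 4])
        assert res.exact
        assert res.p_value == pytest.approx(
            brute_force_permutation_p([5, 6, 7, 8], [1, 2, 3, 4]))
        assert res.p_value == pytest.approx(2 / 70)  # only the two extreme splits

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_equals_brute_force_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 6), rng.integers(2, 6)
        x, y = rng.normal(size=nx), rng.normal(size=ny)
        res = stats.permutation_test(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_permutation_p(x, y))

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.8, 1, 5), rng.normal(0, 1, 5)
        exact = stats.permutation_test(x, y).p_value  # C(10,5)=252 enumerable
        n_perm = 4000
        mc = stats.permutation_test(x, y, n_perm=n_perm, seed=9)
        # force the Monte-Carlo path by shrinking the enumeration budget
        mc = stats.permutation_test(np.r_[x, 0.1], np.r_[y, -0.1],
                                    n_perm=900, seed=9)
        exact = brute_force_permutation_p(np.r_[x, 0.1], np.r_[y, -0.1])
        se = math.sqrt(exact * (1 - exact) / 900)
        assert abs(mc.p_value - exact) <= 3 * se + 2 / 900

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.permutation_test([], [1.0])

    def test_matrix_variant_agrees_with_scalar_on_average(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(0, 1, (30, 12))
        b = rng.lognormal(0, 1, (30, 10))
        _, p = stats.permutation_test_matrix(a, b, n_perm=4000, seed=1)
        assert p.shape == (30,)
        assert (p > 0).all() and (p <= 1).all()
        # compare a few rows against the scalar implementation
        for i in (0, 7, 19):
            scalar = stats.permutation_test(a[i], b[i], n_perm=4000, seed=2)
            se = math.sqrt(scalar.p_value * (1 - scalar.p_value) / 4000)
            assert abs(p[i] - scalar.p_value) <= 4 * se + 2 / 4000


class TestWilcoxonSignedRank:
    def test_all_positive_five(self):
        res = stats.wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.statistic == 15
        assert res.p_value == pytest.approx(2 / 32)

    def test_balanced_symmetric_ties(self):
        res = stats.wilcoxon_signed_rank([1, -1, 2, -2])
        assert res.p_value == 1.0  # W at the null mean: every pattern qualifies

    def test_all_zero_diffs(self):
        assert stats.wilcoxon_signed_rank([0, 0, 0]).p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_untied(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.5, 1, size=int(rng.integers(5, 13)))
        d = d[d != 0]
        mine = stats.wilcoxon_signed_rank(d)
        ref = ss.wilcoxon(d, alternative="two-sided", mode="exact")
        assert mine.exact
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_exact_with_ties_matches_sign_enumeration(self):
        d = np.array([1.0, 1.0, -2.0, 2.0, 3.0])
        ranks = ss.rankdata(np.abs(d))
        mu = ranks.sum() / 2
        w_obs = ranks[d > 0].sum()
        hits = sum(
            abs(np.dot(signs, ranks) - mu) >= abs(w_obs - mu) - 1e-12
            for signs in itertools.product((0, 1), repeat=5))
        assert stats.wilcoxon_signed_rank(d).p_value == pytest.approx(hits / 32)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0.4, 1, size=40)
        mine = stats.wilcoxon_signed_rank(d)
        ref = ss.wilcoxon(d, alternative="two-sided", correction=True,
                          mode="approx")
        assert not mine.exact
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def brute_force_bh(pvals):
    p = np.asarray(pvals, float)
    m = len(p)
    q = np.empty(m)
    order = np.argsort(p, kind="stable")
    for i_pos, i in enumerate(order):
        best = 1.0
        for j_pos in range(i_pos, m):
            j = order[j_pos]
            best = min(best, m * p[j] / (j_pos + 1))
        q[i] = min(best, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert stats.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_arithmetic_progression_flattens(self):
        q = stats.benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05])
        assert q == pytest.approx([0.05] * 5)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 25)))
            np.testing.assert_allclose(
                stats.benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        q = stats.benjamini_hochberg(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.benjamini_hochberg([0.5, 1.2])


class TestFisherExact:
    def test_diagonal_two_by_two(self):
        assert stats.fisher_exact_2x2([[2, 0], [0, 2]]).p_value == \
            pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        assert stats.fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    @pytest.mark.parametrize("table", [
        [[10, 10], [2, 18]], [[3, 7], [9, 1]], [[0, 5], [5, 0]],
        [[12, 2], [3, 11]], [[1, 1], [1, 1]],
    ])
    def test_matches_scipy(self, table):
        mine = stats.fisher_exact_2x2(table)
        _, ref = ss.fisher_exact(table, alternative="two-sided")
        assert mine.p_value == pytest.approx(ref, rel=1e-9)

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_transposition_invariance(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]])
        p0 = stats.fisher_exact_2x2(t).p_value
        assert stats.fisher_exact_2x2(t.T).p_value == pytest.approx(p0)
        assert stats.fisher_exact_2x2(t[::-1]).p_value == pytest.approx(p0)
        assert stats.fisher_exact_2x2(t[:, ::-1]).p_value == pytest.approx(p0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[1, -1], [0, 2]])


class TestChiSquare:
    def test_uniform_tables_p_one(self):
        assert stats.chi_square_independence([[5, 5], [5, 5]]).statistic == 0
        res = stats.chi_square_independence(np.full((3, 3), 4))
        assert res.statistic == 0 and res.p_value == 1.0

    def test_matches_hand_formula(self):
        t = np.array([[20, 5], [5, 20]])
        row, col, n = t.sum(1), t.sum(0), t.sum()
        expected = np.outer(row, col) / n
        x2_hand = ((t - expected) ** 2 / expected).sum()
        res = stats.chi_square_independence(t)
        assert res.statistic == pytest.approx(x2_hand)
        chi2_ref, p_ref, _, _ = ss.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(chi2_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_zero_expected_advises_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            stats.chi_square_independence([[0, 0], [1, 2]])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = stats.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.p_value == pytest.approx(
            ss.kruskal([1, 2, 3], [1, 2, 3], [1, 2, 3]).pvalue)

    def test_hand_ranks_no_ties(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        # ranks 1..6; H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7
        h_hand = 12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21
        res = stats.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h_hand)

    def test_tie_correction_matches_scipy(self):
        groups = [[1, 1, 1], [1, 1, 2]]
        res = stats.kruskal_wallis(groups)
        ref = ss.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis([[1, 2, 3]])


class TestManovaWilks:
    def test_identical_group_means_lambda_one(self):
        y = np.array([[1.0, 2.0], [3.0, 0.0], [1.0, 2.0], [3.0, 0.0],
                      [2.0, 4.0], [2.0, 4.0]])
        res = stats.manova_wilks(y, ["a", "a", "b", "b", "a", "b"])
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)

    def test_single_response_reduces_to_anova(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        res = stats.manova_wilks(y[:, None], g)
        f_ref, p_ref = ss.f_oneway(y[:10], y[10:20], y[20:])
        assert res.f_statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert res.per_response_f[0] == pytest.approx(f_ref)

    def test_two_response_matches_scatter_matrix_oracle(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(24, 2))
        y[:12] += [0.8, -0.4]
        g = np.repeat(["a", "b"], 12)
        res = stats.manova_wilks(y, g)
        # independent oracle: explicit W and B scatter matrices
        grand = y.mean(0)
        w = sum((y[g == lvl] - y[g == lvl].mean(0)).T
                @ (y[g == lvl] - y[g == lvl].mean(0)) for lvl in ("a", "b"))
        b = sum((g == lvl).sum()
                * np.outer(y[g == lvl].mean(0) - grand,
                           y[g == lvl].mean(0) - grand) for lvl in ("a", "b"))
        lam = np.linalg.det(w) / np.linalg.det(w + b)
        assert res.wilks_lambda == pytest.approx(lam)

    def test_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(12)
        y = rng.normal(size=(30, 2))
        g = np.repeat(["a", "b", "c"], 10)
        y[:10] += 0.9
        res = stats.manova_wilks(y, g)
        import pandas as pd
        df = pd.DataFrame({"y1": y[:, 0], "y2": y[:, 1], "g": g})
        sm = MANOVA.from_formula("y1 + y2 ~ g", data=df)
        tbl = sm.mv_test().results["g"]["stat"]
        assert res.wilks_lambda == pytest.approx(tbl.loc["Wilks' lambda", "Value"])
        assert res.p_value == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"],
                                            abs=1e-8)

    def test_constant_column_is_singular(self):
        y = np.ones((12, 2))
        y[:, 0] = np.arange(12)
        with pytest.raises(ValueError, match="singular"):
            stats.manova_wilks(y, np.repeat(["a", "b"], 6))
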