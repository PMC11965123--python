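"""Unit and property tests for the statistical kernel."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from lefpon.stats import (
    ContingencyTable,
    SeparationError,
    fit_logistic,
    hwe_test,
    kruskal_wallis,
    mann_whitney,
    odds_ratio_woolf,
    pearson_chi2,
    spearman_corr,
)


def _table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        counts,
        tuple(f"r{i}" for i in range(counts.shape[0])),
        tuple(f"c{j}" for j in range(counts.shape[1])),
    )


def brute_force_chi2(counts):
    """Independent oracle: explicit expected counts, cell-by-cell sum."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    return ((counts - expected) ** 2 / expected).sum()


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "counts, statistic, df",
        [
            # published codominant genotype-by-response counts
            ([[50, 63, 34], [20, 49, 24]], 4.4042, 2),
            ([[10, 10], [10, 10]], 0.0, 1),  # proportional rows
        ],
    )
    def test_known_values(self, counts, statistic, df):
        res = pearson_chi2(_table(counts))
        assert res.statistic == pytest.approx(statistic, abs=5e-4)
        assert res.df == df

    def test_matches_expected_count_oracle(self):
        # expected counts for [[5,1],[2,8]] are 3.5/2.5/3.5/6.5
        counts = [[5, 1], [2, 8]]
        expected = np.outer([6, 10], [7, 9]) / 16
        assert np.allclose(expected, [[42 / 16, 54 / 16], [70 / 16, 90 / 16]])
        res = pearson_chi2(_table(counts))
        assert res.statistic == pytest.approx(brute_force_chi2(counts), abs=1e-12)

    def test_zero_margin_names_the_degenerate_margin(self):
        with pytest.raises(ValueError, match="column margin 'c1'"):
            pearson_chi2(_table([[5, 0], [3, 0]]))
        with pytest.raises(ValueError, match="row margin 'r0'"):
            pearson_chi2(_table([[0, 0], [3, 4]]))

    def test_zero_grand_total_rejected_by_table(self):
        with pytest.raises(ValueError, match="grand total"):
            _table([[0, 0], [0, 0]])

    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_invariant_under_row_and_column_permutation(self, rows):
        counts = np.array(rows)
        rng = np.random.default_rng(0)
        perm = counts[rng.permutation(counts.shape[0])][:, rng.permutation(counts.shape[1])]
        assert pearson_chi2(_table(counts)).statistic == pytest.approx(
            pearson_chi2(_table(perm)).statistic
        )

    def test_null_p_values_approximately_uniform(self):
        """Rejection rate at alpha=0.05 within [0.03, 0.07] under the null."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 2000
        probs = np.outer([0.5, 0.5], [0.3, 0.7]).ravel()  # independent margins
        for _ in range(n_rep):
            counts = rng.multinomial(200, probs).reshape(2, 2)
            if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
                continue
            rejections += pearson_chi2(_table(counts)).p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestOddsRatioWoolf:
    def test_published_allele_odds_ratio(self):
        res = odds_ratio_woolf(131, 163, 97, 89)
        assert res.or_value == pytest.approx(0.737, abs=5e-4)
        assert res.ci_low == pytest.approx(0.510, abs=5e-4)
        assert res.ci_high == pytest.approx(1.066, abs=5e-4)

    def test_uniform_table_is_unity(self):
        assert odds_ratio_woolf(1, 1, 1, 1).or_value == 1.0

    def test_haldane_correction_closed_form(self):
        res = odds_ratio_woolf(0, 5, 3, 7, haldane=True)
        assert res.or_value == pytest.approx((0.5 * 7.5) / (5.5 * 3.5))

    def test_zero_cell_without_haldane_instructs_correction(self):
        with pytest.raises(ValueError, match="haldane"):
            odds_ratio_woolf(0, 5, 3, 7)

    @given(st.tuples(*[st.integers(min_value=1, max_value=200)] * 4))
    def test_swap_reciprocal_identity(self, cells):
        a, b, c, d = cells
        fwd = odds_ratio_woolf(a, b, c, d)
        rev = odds_ratio_woolf(b, a, d, c)
        assert fwd.or_value * rev.or_value == pytest.approx(1.0, abs=1e-12)
        # the CI is symmetric on the log scale too
        assert fwd.ci_low * rev.ci_high == pytest.approx(1.0, rel=1e-10)


class TestFitLogistic:
    def test_intercept_only_balanced_outcome(self):
        y = np.array([0, 1] * 20)
        fit = fit_logistic(np.ones((40, 1)), y, names=["const"])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-10)

    def test_single_binary_predictor_matches_woolf(self):
        """MLE with one binary predictor is the closed-form 2x2 odds ratio."""
        a, b, c, d = 30, 45, 25, 15  # exposed/unexposed x case/control
        x = np.r_[np.ones(a + c), np.zeros(b + d)]
        y = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
        fit = fit_logistic(np.column_stack([np.ones_like(x), x]), y, names=["const", "x"])
        ref = odds_ratio_woolf(a, b, c, d)
        assert fit["x"]["or"] == pytest.approx(ref.or_value, abs=1e-6)
        assert fit["x"]["se"] == pytest.approx(
            np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6
        )
        assert fit["x"]["ci_low"] == pytest.approx(ref.ci_low, abs=1e-6)

    def test_perfect_separation_raises(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        design = np.column_stack([np.ones(20), y])
        with pytest.raises(SeparationError):
            fit_logistic(design, y)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(300), rng.normal(size=300), rng.integers(0, 2, 300)])
        eta = 0.3 - 0.8 * X[:, 1] + 0.5 * X[:, 2]
        y = rng.random(300) < 1 / (1 + np.exp(-eta))
        fit = fit_logistic(X, y.astype(int))
        sm_fit = sm.Logit(y.astype(int), X).fit(disp=0)
        assert fit.coefficients == pytest.approx(sm_fit.params, abs=1e-6)
        assert fit.standard_errors == pytest.approx(sm_fit.bse, abs=1e-6)

    def test_non_convergence_is_flagged_not_raised(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = rng.integers(0, 2, 100)
        fit = fit_logistic(X, y, max_iter=1)
        assert not fit.converged

    def test_outcome_must_be_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            fit_logistic(np.ones((5, 1)), np.array([0, 1, 2, 0, 1]))


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, rho",
        [((1, 2, 3), (10, 20, 30), 1.0), ((1, 2, 3), (3, 2, 1), -1.0)],
    )
    def test_monotone_vectors(self, x, y, rho):
        assert spearman_corr(x, y)[0] == pytest.approx(rho)

    def test_matches_midrank_pearson_oracle(self):
        x, y = [1, 2, 2, 4], [7, 5, 6, 1]
        rx, ry = sps.rankdata(x), sps.rankdata(y)  # mid-ranks for ties
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y)[0] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, _ = kruskal_wallis([[1, 2, 3]] * 3)
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_sum_formula(self):
        # groups {1,2},{3,4},{5,6}: ranks 1..6, rank sums 3/7/11, no ties
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        oracle = 12 / (6 * 7) * (9 / 2 + 49 / 2 + 121 / 2) - 3 * 7
        assert h == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(sps.chi2.sf(oracle, 2), abs=1e-12)

    def test_two_groups_match_mann_whitney_p(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        _, p_kw = kruskal_wallis([x, y])
        _, p_mw = mann_whitney(x, y)
        assert p_kw == pytest.approx(p_mw, abs=1e-10)

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([[2, 2], [2, 2, 2]])


class TestMannWhitney:
    def test_complete_separation_gives_zero_wins(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 8, 5).astype(float)
        y = rng.integers(0, 8, 5).astype(float)
        wins = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        u, _ = mann_whitney(x, y)
        assert u == pytest.approx(wins)


class TestHWE:
    def test_exact_proportions_give_zero(self):
        assert hwe_test(25, 50, 25).statistic == pytest.approx(0.0, abs=1e-12)

    def test_pooled_cohort_counts_consistent_with_equilibrium(self):
        res = hwe_test(70, 112, 58)
        assert res.statistic == pytest.approx(0.993, abs=5e-4)
        assert res.p == pytest.approx(0.319, abs=5e-4)
        assert res.p > 0.05

    def test_maximal_disequilibrium(self):
        res = hwe_test(50, 0, 50)
        assert res.p < 1e-10

    def test_monomorphic_sample_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_test(100, 0, 0)

    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=2, max_value=60))
    def test_zero_exactly_at_hardy_weinberg_expectations(self, k, m):
        # counts (k^2, 2km, m^2) sit exactly at HW proportions
        assert hwe_test(k * k, 2 * k * m, m * m).statistic == pytest.approx(0.0, abs=1e-9)
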