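"""Group-level nonparametric comparison of per-foot risk-region areas."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plantarstat.cohort import (
    AreaComparison,
    compare_conditions,
    count_optimal,
    descriptives,
    friedman_test,
    wilcoxon_signed_rank,
)
from plantarstat.io import AreaTable

from conftest import synthetic_cohort_table


def table_from_matrix(matrix, conditions=("A", "B", "C")):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i:02d}", "left") for i in range(len(matrix))],
        names=["subject", "side"],
    )
    return AreaTable(pd.DataFrame(matrix, index=idx, columns=list(conditions)[: matrix.shape[1]]))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def wilcoxon_signflip_p(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([1, -1], repeat=len(d))
    ])
    return min(1.0, 2 * min((ws <= obs).mean(), (ws >= obs).mean()))


def friedman_permutation_p(matrix):
    """Exhaustive within-row permutation p, sharing only the rank definition."""
    from plantarstat.cohort import _friedman_chi2

    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    obs = _friedman_chi2(matrix)
    count = total = 0
    for perms in itertools.product(itertools.permutations(range(k)), repeat=n):
        permuted = np.array([matrix[i, list(p)] for i, p in enumerate(perms)])
        if _friedman_chi2(permuted) >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_identical_samples(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero"):
            w, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_signflip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(2, 4, 8)
        y = rng.normal(0, 4, 8)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(wilcoxon_signflip_p(x - y), abs=1e-12)

    def test_tied_data_falls_back_to_approximation(self):
        x = np.array([5.0, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27])
        y = x - np.array([2.0, 2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4])  # tied |d|
        w, p = wilcoxon_signed_rank(x, y)
        assert 0 < p < 0.01  # all positive differences: strongly significant

    def test_strong_shift_below_headline_bound(self, cohort_table):
        data = cohort_table.require_complete(["FI", "TCCI"])
        _, p = wilcoxon_signed_rank(
            data["FI"].to_numpy(), data["TCCI"].to_numpy()
        )
        assert p < 1e-4


class TestFriedman:
    def test_identical_conditions(self):
        table = table_from_matrix(np.tile([[3.0, 3.0, 3.0]], (6, 1)))
        chi2, df, p = friedman_test(table, ["A", "B", "C"])
        assert chi2 == 0.0
        assert df == 2
        assert p == 1.0

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(21)
        m = rng.uniform(0, 30, (10, 3))
        table = table_from_matrix(m)
        chi2, _, p = friedman_test(table, ["A", "B", "C"])
        chi2_sp, p_sp = stats.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
        assert chi2 == pytest.approx(chi2_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-12)

    def test_approx_p_near_permutation_for_strong_effect(self):
        # effect-strong 5x3 table: the chi-square approximation is accurate
        # in the significant tail where this analysis operates
        m = np.array([
            [26.0, 9.0, 4.0],
            [31.0, 12.0, 7.0],
            [18.0, 8.0, 2.0],
            [24.0, 16.0, 5.0],
            [29.0, 10.0, 6.0],
        ])
        table = table_from_matrix(m)
        _, _, p_approx = friedman_test(table, ["A", "B", "C"])
        assert abs(p_approx - friedman_permutation_p(m)) <= 0.02

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_mode_equals_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.round(rng.uniform(0, 8, (5, 3)))  # ties included
        table = table_from_matrix(m)
        _, _, p_exact = friedman_test(table, ["A", "B", "C"], method="exact")
        assert p_exact == pytest.approx(friedman_permutation_p(m), abs=1e-12)

    def test_incomplete_rows_rejected(self):
        df = table_from_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]).data
        df.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_test(AreaTable(df), ["A", "B", "C"])

    def test_synthetic_cohort_strongly_significant(self, cohort_table):
        _, _, p = friedman_test(cohort_table, ["FI", "TCCI", "CADCAM"])
        assert p < 1e-10


class TestCompareConditions:
    def test_identical_conditions_null_results(self):
        m = np.column_stack([np.arange(1.0, 9), np.arange(1.0, 9)])
        comp = compare_conditions(table_from_matrix(m, ("A", "B")), ["A", "B"])
        (pair,) = comp.pairwise
        assert pair.p == 1.0
        assert pair.mean_difference_cm2 == 0.0

    def test_uniform_shift_mean_difference(self):
        base = np.arange(5.0, 13)
        m = np.column_stack([base, base - 3.0])
        comp = compare_conditions(table_from_matrix(m, ("orig", "shifted")),
                                  ["orig", "shifted"])
        assert comp.pairwise[0].mean_difference_cm2 == pytest.approx(3.0)

    def test_bonferroni_level_three_conditions(self, cohort_table):
        comp = compare_conditions(cohort_table, ["FI", "TCCI", "CADCAM"])
        assert comp.k == 3
        assert len(comp.pairwise) == 3
        assert comp.alpha_pairwise == pytest.approx(0.0166667, abs=1e-6)
        assert comp.friedman_df == 2

    def test_row_order_invariance(self, cohort_table):
        shuffled = AreaTable(
            cohort_table.data.sample(frac=1.0, random_state=5)
        )
        a = compare_conditions(cohort_table, ["FI", "TCCI", "CADCAM"])
        b = compare_conditions(shuffled, ["FI", "TCCI", "CADCAM"])
        assert a.friedman_chi2 == pytest.approx(b.friedman_chi2)
        for ra, rb in zip(a.pairwise, b.pairwise):
            assert ra.p == pytest.approx(rb.p)
            assert ra.mean_difference_cm2 == pytest.approx(rb.mean_difference_cm2)


class TestOptimalAndDescriptives:
    def test_count_optimal_examples(self):
        table = table_from_matrix(
            np.array([[0.0], [1.25], [0.0], [4.5]]), ("TCCI",)
        )
        assert count_optimal(table, "TCCI") == 2
        all_zero = table_from_matrix(np.zeros((4, 1)), ("TCCI",))
        assert count_optimal(all_zero, "TCCI") == 4

    def test_optimal_plus_nonoptimal_equals_n(self, cohort_table):
        n = cohort_table.n_feet
        for cond in ("FI", "TCCI", "CADCAM"):
            k = count_optimal(cohort_table, cond)
            non_optimal = int((cohort_table.data[cond] > 0).sum())
            assert k + non_optimal == n

    def test_two_value_closed_form(self):
        desc = descriptives(table_from_matrix(np.array([[2.0], [4.0]]), ("FI",)))
        row = desc.table.loc["FI"]
        assert row["mean"] == pytest.approx(3.0)
        assert row["sd"] == pytest.approx(1.41421, abs=1e-4)
        assert row["median"] == pytest.approx(3.0)
        assert row["max"] == pytest.approx(4.0)

    def test_single_row_sd_not_applicable(self):
        desc = descriptives(table_from_matrix(np.array([[7.0]]), ("FI",)))
        assert np.isnan(desc.table.loc["FI", "sd"])
        assert desc.table.loc["FI", "mean"] == 7.0

    def test_max_at_least_median(self, cohort_table):
        desc = descriptives(cohort_table).table
        assert np.all(desc["max"] >= desc["median"])


class TestAreaComparisonModel:
    def test_fit_and_summary(self, cohort_table):
        res = AreaComparison(cohort_table, ["FI", "TCCI", "CADCAM"]).fit()
        text = res.summary()
        assert "Friedman" in text
        assert "Optimal offloading" in text
        frame = res.pairwise_frame()
        assert list(frame["condition_1"]) == ["FI", "FI", "TCCI"]
        # custom insoles shrink areas relative to flat insole
        assert (frame.loc[:1, "mean_difference_cm2"] > 0).all()

    def test_from_dataframe_roundtrip(self, cohort_table):
        res = AreaComparison.from_dataframe(
            cohort_table.data.reset_index(), ["FI", "TCCI"]
        ).fit()
        assert res.comparison.k == 2
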