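"""Within-patient ranking and the contingency statistics battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.contingency_tables import Table2x2

from pnquant.ranking import (
    cochran_heterogeneity,
    odds_ratio_woolf,
    pearson_chi_square,
    rank_rate_table,
    rank_within_patient,
    spearman_rank_corr,
    top_vs_last_table,
)


def _cohort(beta1s, patient="P1", ids=None):
    ids = ids or [f"E{i}" for i in range(len(beta1s))]
    return pd.DataFrame(
        {"patient_id": patient, "embryo_id": ids, "beta1": beta1s}
    )


class TestRanking:
    def test_descending_rank_order(self):
        ranked = rank_within_patient(_cohort([5.1, 3.0, 4.2]))
        by_id = ranked.set_index("embryo_id")["rank"]
        assert list(by_id[["E0", "E1", "E2"]]) == [1, 3, 2]

    def test_pooled_labels_after_k(self):
        ranked = rank_within_patient(_cohort(list(range(12, 0, -1))), pool_after=10)
        labels = list(ranked["pooled_rank_label"])
        assert labels[:10] == [str(i) for i in range(1, 11)]
        assert labels[10:] == [">10", ">10"]

    def test_ties_break_by_embryo_id(self):
        ranked = rank_within_patient(_cohort([4.0, 4.0], ids=["e2", "e1"]))
        by_id = ranked.set_index("embryo_id")["rank"]
        assert by_id["e1"] == 1 and by_id["e2"] == 2

    def test_duplicate_embryo_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_within_patient(_cohort([1.0, 2.0], ids=["e1", "e1"]))

    def test_non_finite_beta1_rejected(self):
        with pytest.raises(ValueError):
            rank_within_patient(_cohort([1.0, np.nan]))


class TestRateTable:
    def test_formatted_cell(self):
        ranked = pd.DataFrame(
            {
                "pooled_rank_label": ["1"] * 155,
                "outcome": [True] * 102 + [False] * 53,
            }
        )
        table = rank_rate_table(ranked)
        assert table.iloc[0]["cell"] == "102/155 (65.81)"

    def test_strata_ordered_with_pooled_last(self):
        ranked = pd.DataFrame(
            {
                "pooled_rank_label": [">8", "2", "1", "10"],
                "outcome": [True, False, True, True],
            }
        )
        table = rank_rate_table(ranked)
        assert list(table["rank"]) == ["1", "2", "10", ">8"]

    def test_missing_outcome_rejected(self):
        ranked = pd.DataFrame({"pooled_rank_label": ["1"], "outcome": [None]})
        with pytest.raises(ValueError):
            rank_rate_table(ranked)


class TestWoolfOddsRatio:
    def test_matches_statsmodels_oracle(self):
        res = odds_ratio_woolf(90, 65, 70, 85)
        oracle = Table2x2(np.array([[90, 65], [70, 85]]))
        assert res.estimate == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = oracle.oddsratio_confint(0.05)
        # same construction up to the z quantile's 5th decimal
        assert res.ci_low == pytest.approx(lo, rel=1e-5)
        assert res.ci_high == pytest.approx(hi, rel=1e-5)

    def test_balanced_table_is_unity(self):
        assert odds_ratio_woolf(30, 40, 30, 40).estimate == pytest.approx(1.0)

    def test_reciprocal_symmetry(self):
        a = odds_ratio_woolf(90, 65, 70, 85)
        b = odds_ratio_woolf(65, 90, 85, 70)
        assert a.estimate * b.estimate == pytest.approx(1.0, rel=1e-12)
        assert a.ci_low == pytest.approx(1.0 / b.ci_high, rel=1e-12)

    def test_ci_contains_estimate_and_shrinks_with_counts(self):
        small = odds_ratio_woolf(9, 6, 7, 8)
        big = odds_ratio_woolf(90, 60, 70, 80)
        for r in (small, big):
            assert r.ci_low <= r.estimate <= r.ci_high
        assert (big.ci_high / big.ci_low) < (small.ci_high / small.ci_low)

    def test_zero_cell_haldane_flagged(self):
        res = odds_ratio_woolf(10, 0, 5, 5)
        assert res.corrected
        with pytest.raises(ValueError):
            odds_ratio_woolf(10, 0, 5, 5, haldane_if_zero=False)


class TestPearsonChiSquare:
    def test_hand_expanded_2x2(self):
        # O = [[10,20],[30,40]]; E from margins; chi2 = sum (O-E)^2/E
        table = np.array([[10, 20], [30, 40]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        res = pearson_chi_square(table)
        assert res.estimate == pytest.approx(by_hand, rel=1e-12)
        assert res.df == 1

    def test_rows_proportional_to_margins_zero(self):
        res = pearson_chi_square(np.array([[10, 20], [20, 40], [5, 10]]))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_invariance(self, rng):
        table = rng.integers(5, 50, size=(6, 2))
        a = pearson_chi_square(table).estimate
        b = pearson_chi_square(table[::-1]).estimate
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square(np.array([[0, 0], [5, 10]]))


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_rank_corr(x, x).estimate == pytest.approx(1.0)
        assert spearman_rank_corr(x, [-v for v in x]).estimate == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self, rng):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0, 6.0, 8.0]
        # oracle: mid-rank then Pearson correlation of the ranks
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rank_corr(x, y).estimate == pytest.approx(oracle, rel=1e-12)

    def test_constant_vector_flagged_not_raised(self):
        res = spearman_rank_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.estimate)


class TestCochranHeterogeneity:
    def test_identical_groups_no_heterogeneity(self):
        res = cochran_heterogeneity([(10.0, 1.0, 4)] * 5)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.I2_pct == 0.0
        assert res.df == 4

    def test_two_group_hand_computation(self):
        # w = n/sd^2 = 4 each; pooled mean 12; Q = 4*4 + 4*4 = 32
        res = cochran_heterogeneity([(10.0, 1.0, 4), (14.0, 1.0, 4)])
        assert res.Q == pytest.approx(32.0, rel=1e-12)
        assert res.df == 1
        assert res.I2_pct == pytest.approx((32 - 1) / 32 * 100, rel=1e-12)

    def test_strong_between_group_spread_high_i2(self, rng):
        groups = [(m, 1.0, 5) for m in rng.normal(100, 30, size=30)]
        res = cochran_heterogeneity(groups)
        assert res.I2_pct > 90.0

    def test_zero_variance_group_capped_and_flagged(self):
        res = cochran_heterogeneity(
            [(10.0, 0.0, 4), (12.0, 1.0, 4), (14.0, 1.0, 4)], group_ids=["a", "b", "c"]
        )
        assert res.flagged_groups == ["a"]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            cochran_heterogeneity([(10.0, 1.0, 4)])


class TestTopVsLast:
    def test_counts_from_two_patients(self):
        ranked = pd.DataFrame(
            {
                "patient_id": ["P1"] * 3 + ["P2"] * 2,
                "embryo_id": list("abcde"),
                "beta1": [3.0, 2.0, 1.0, 5.0, 4.0],
                "rank": [1, 2, 3, 1, 2],
                "outcome": [True, True, False, False, True],
            }
        )
        assert top_vs_last_table(ranked) == (1, 1, 1, 1)

    def test_small_patients_skipped(self):
        ranked = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "embryo_id": ["a"],
                "beta1": [1.0],
                "rank": [1],
                "outcome": [True],
            }
        )
        assert top_vs_last_table(ranked) == (0, 0, 0, 0)
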