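"""Decile stratification and the Mantel-Haenszel pooled risk ratio."""

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable

from grace_recal.errors import PreconditionError, UndefinedStatisticError
from grace_recal.mh import (
    StratumTable,
    assign_deciles,
    mh_pooled_rr,
    observed_by_band,
    observed_vs_predicted_by_decile,
    stratum_tables,
)


def rank_sort_oracle(risks: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Independent decile assignment: stable sort, then chunk the order."""
    order = sorted(range(len(risks)), key=lambda i: (risks[i], i))
    n = len(risks)
    labels = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        labels[idx] = rank * n_bins // n + 1
    return labels


class TestAssignDeciles:
    def test_ten_distinct_values_one_per_bin(self):
        risks = np.arange(1, 11) / 100
        assert list(assign_deciles(risks)) == list(range(1, 11))

    def test_twenty_observations_two_per_bin(self):
        risks = np.linspace(0.01, 0.2, 20)
        labels = assign_deciles(risks)
        assert all((labels == k).sum() == 2 for k in range(1, 11))

    def test_heavy_ties_split_by_stable_order(self):
        rng = np.random.default_rng(0)
        risks = np.where(rng.random(1000) < 0.5, 0.05, rng.random(1000))
        labels = assign_deciles(risks)
        counts = np.bincount(labels)[1:]
        assert all(counts == 100)
        np.testing.assert_array_equal(labels, rank_sort_oracle(risks))

    def test_too_few_observations(self):
        with pytest.raises(PreconditionError):
            assign_deciles([0.1] * 9)

    def test_bin_sizes_differ_by_at_most_one(self):
        risks = np.random.default_rng(1).random(1003)
        counts = np.bincount(assign_deciles(risks))[1:]
        assert counts.max() - counts.min() <= 1


class TestStratumTables:
    def test_hand_tabulated(self):
        deciles = [1, 1, 2, 2]
        group = [True, False, True, False]
        died = [True, False, False, True]
        tables = stratum_tables(deciles, group, died)
        assert tables[0] == StratumTable(a=1, n1=1, b=0, n0=1)
        assert tables[1] == StratumTable(a=0, n1=1, b=1, n0=1)

    def test_single_group_degenerate(self):
        tables = stratum_tables([1, 1], [True, True], [True, False])
        assert tables[0].n0 == 0 and tables[0].n1 == 2 and tables[0].a == 1

    def test_death_conservation(self):
        rng = np.random.default_rng(5)
        died = rng.random(500) < 0.3
        tables = stratum_tables(rng.integers(1, 11, 500), rng.random(500) < 0.2, died)
        assert sum(t.a + t.b for t in tables) == died.sum()


class TestMHPooledRR:
    def test_single_stratum_equals_crude_rr(self):
        res = mh_pooled_rr([StratumTable(a=10, n1=100, b=5, n0=100)])
        assert res.rr == pytest.approx(2.0)

    def test_homogeneous_strata_preserve_rr(self):
        strata = [StratumTable(a=4, n1=20, b=2, n0=20),
                  StratumTable(a=10, n1=50, b=10, n0=100)]
        # both strata have within-stratum RR 2
        assert mh_pooled_rr(strata).rr == pytest.approx(2.0)

    def test_two_stratum_hand_value(self):
        # oracle: num = 8*100/140 + 30*50/110 = 1490/77;
        #         den = 10*40/140 + 5*60/110 = 430/77; RR = 149/43
        strata = [StratumTable(a=8, n1=40, b=10, n0=100),
                  StratumTable(a=30, n1=60, b=5, n0=50)]
        assert mh_pooled_rr(strata).rr == pytest.approx(149 / 43, rel=1e-12)

    def test_reorder_invariance(self):
        strata = [StratumTable(a=8, n1=40, b=10, n0=100),
                  StratumTable(a=30, n1=60, b=5, n0=50),
                  StratumTable(a=1, n1=30, b=4, n0=60)]
        res1 = mh_pooled_rr(strata)
        res2 = mh_pooled_rr(strata[::-1])
        assert res1.rr == pytest.approx(res2.rr)
        assert res1.ci_low == pytest.approx(res2.ci_low)

    def test_identical_risks_give_unity_and_ci_covers_one(self):
        strata = [StratumTable(a=5, n1=50, b=10, n0=100),
                  StratumTable(a=20, n1=100, b=4, n0=20)]
        res = mh_pooled_rr(strata)
        assert res.rr == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_point_estimate_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(7)
        strata = []
        sm_tables = []
        for _ in range(6):
            n1, n0 = int(rng.integers(30, 200)), int(rng.integers(30, 200))
            a, b = int(rng.integers(1, n1 // 2)), int(rng.integers(1, n0 // 2))
            strata.append(StratumTable(a=a, n1=n1, b=b, n0=n0))
            sm_tables.append(np.array([[a, n1 - a], [b, n0 - b]]))
        res = mh_pooled_rr(strata)
        oracle = StratifiedTable(np.dstack(sm_tables).astype(float))
        assert res.rr == pytest.approx(oracle.riskratio_pooled, rel=1e-10)

    def test_ci_matches_frozen_metafor_oracle(self):
        # frozen from metafor::rma.mh(measure="RR") (Greenland-Robins SEs):
        # ai=(63,112,19), n1i=(210,340,95), ci=(41,88,11), n0i=(190,310,120)
        strata = [StratumTable(a=63, n1=210, b=41, n0=190),
                  StratumTable(a=112, n1=340, b=88, n0=310),
                  StratumTable(a=19, n1=95, b=11, n0=120)]
        res = mh_pooled_rr(strata)
        assert res.rr == pytest.approx(1.2972924735, abs=1e-9)
        assert res.ci_low == pytest.approx(1.0781480944, abs=1e-9)
        assert res.ci_high == pytest.approx(1.5609801385, abs=1e-9)

    def test_empty_group_strata_dropped_and_counted(self):
        strata = [StratumTable(a=10, n1=100, b=5, n0=100),
                  StratumTable(a=3, n1=30, b=0, n0=0)]
        res = mh_pooled_rr(strata)
        assert res.n_strata == 1 and res.n_strata_dropped == 1
        assert res.rr == pytest.approx(2.0)

    def test_no_unexposed_deaths_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mh_pooled_rr([StratumTable(a=5, n1=50, b=0, n0=50)])

    def test_no_usable_strata(self):
        with pytest.raises(UndefinedStatisticError):
            mh_pooled_rr([StratumTable(a=5, n1=50, b=0, n0=0)])


class TestObservedTables:
    def test_calibrated_outcomes_match_predictions_by_decile(self):
        rng = np.random.default_rng(10)
        risks = rng.beta(1.2, 8, 40_000)
        died = rng.random(40_000) < risks
        group = rng.random(40_000) < 0.2
        table = observed_vs_predicted_by_decile(risks, died, group)
        deciles = assign_deciles(risks)
        for _, row in table.iterrows():
            in_k = deciles == row["decile"]
            # table cells equal a direct tally ...
            assert row["observed_group"] == pytest.approx(died[in_k & group].mean())
            assert row["observed_non_group"] == pytest.approx(died[in_k & ~group].mean())
            # ... and observed tracks predicted when outcomes are Bernoulli(risk)
            pooled_obs = died[in_k].mean()
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["n"])
            assert abs(pooled_obs - row["mean_predicted"]) < 4 * se

    def test_all_survivors_give_zero_observed(self):
        risks = np.linspace(0.01, 0.5, 50)
        table = observed_vs_predicted_by_decile(risks, np.zeros(50, bool),
                                                np.zeros(50, bool))
        assert (table["observed_non_group"] == 0).all()

    def test_empty_group_cell_is_missing_not_zero(self):
        risks = np.linspace(0.01, 0.5, 50)
        group = np.zeros(50, bool)  # no group members anywhere
        table = observed_vs_predicted_by_decile(risks, np.zeros(50, bool), group)
        assert table["observed_group"].isna().all()

    def test_band_table_single_death_in_high(self):
        table = observed_by_band(np.array([0.5]), np.array([True]), np.array([True]))
        high = table.set_index("band").loc["high"]
        assert high["observed_group"] == 1.0
        assert np.isnan(high["observed_non_group"])

    def test_band_with_no_records_is_missing(self):
        table = observed_by_band(np.array([0.5, 0.4]), np.array([True, False]),
                                 np.array([True, False]))
        low = table.set_index("band").loc["low"]
        assert np.isnan(low["observed_group"]) and np.isnan(low["observed_non_group"])

    def test_calibrated_band_mortality_within_band_interval(self):
        rng = np.random.default_rng(11)
        risks = rng.uniform(0.0, 0.12, 50_000)
        died = rng.random(50_000) < risks
        group = rng.random(50_000) < 0.15
        table = observed_by_band(risks, died, group).set_index("band")
        assert 0.0 <= table.loc["low", "observed_non_group"] < 0.03
        assert 0.025 <= table.loc["moderate", "observed_non_group"] <= 0.065
        assert table.loc["high", "observed_non_group"] > 0.06
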