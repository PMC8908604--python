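import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crcsig.datasets import reference_crosstab
from crcsig.stats import (
    ClinicalTable,
    StatsError,
    correlation_matrix,
    median_split_quadrants,
    round_half_up,
    table_one,
    trend_test,
    two_group_test,
    _trend_statistic,
)


class TestCorrelationMatrix:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        cm = correlation_matrix(df)
        assert cm.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_rank_reversal(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -(x**3)})
        cm = correlation_matrix(df)
        assert cm.rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self, rng):
        n, rho = 500, 0.8
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        cm = correlation_matrix(pd.DataFrame(z, columns=["a", "b"]))
        assert cm.rho.loc["a", "b"] == pytest.approx(rho, abs=0.05)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        cm = correlation_matrix(df)
        assert np.isnan(cm.rho.loc["x", "c"])

    def test_symmetry_diag_and_pairwise_n(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, np.nan, 5.0], "y": [2.0, 1.0, 4.0, 3.0, np.nan]}
        )
        cm = correlation_matrix(df)
        assert cm.rho.loc["x", "x"] == 1.0
        assert cm.n.loc["x", "y"] == 3
        assert cm.rho.equals(cm.rho.T)

    @given(st.sampled_from(["exp", "cube", "logit"]))
    @settings(derandomize=True, max_examples=3)
    def test_spearman_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = 0.7 * x + rng.normal(size=60)
        f = {"exp": np.exp, "cube": lambda v: v**3,
             "logit": lambda v: 1 / (1 + np.exp(-v))}[transform]
        base = correlation_matrix(pd.DataFrame({"x": x, "y": y})).rho.loc["x", "y"]
        trans = correlation_matrix(pd.DataFrame({"x": f(x), "y": y})).rho.loc["x", "y"]
        assert base == pytest.approx(trans, abs=1e-12)


def _mw_enumeration_p(a, b):
    """Brute-force exact two-sided Mann-Whitney p over all assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    def u_stat(idx):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return u1
    u_obs = u_stat(range(n1))
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        u = u_stat(idx)
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestTwoGroup:
    def test_identical_groups_p_one(self):
        stat, p = two_group_test(
            [1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3, test="mann_whitney"
        )
        assert p == pytest.approx(1.0)

    def test_disjoint_groups_exact_p(self):
        stat, p = two_group_test(
            [1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3, test="mann_whitney"
        )
        assert p == pytest.approx(2 / 20)

    def test_exact_branch_matches_enumeration_exhaustively(self):
        # every split of 8 distinct values into groups of n1 = 1..4
        values = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8])
        n = len(values)
        for n1 in range(1, 5):
            for idx in itertools.combinations(range(n), n1):
                groups = np.array(["b"] * n, dtype=object)
                groups[list(idx)] = "a"
                _, p = two_group_test(values, groups, test="mann_whitney")
                expected = _mw_enumeration_p(values[list(idx)],
                                             np.delete(values, list(idx)))
                assert p == pytest.approx(expected, abs=1e-9), (n1, idx)

    def test_label_swap_invariance(self, rng):
        v = rng.normal(size=30)
        g = rng.choice(["x", "y"], size=30)
        for test in ("mann_whitney", "welch_t"):
            _, p1 = two_group_test(v, g, test=test)
            swapped = np.where(g == "x", "y", "x")
            _, p2 = two_group_test(v, swapped, test=test)
            assert p1 == pytest.approx(p2)

    def test_welch_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(size=15)
            b = rng.normal(scale=2.0, size=10)  # unequal variances, equal means
            _, p = two_group_test(
                np.concatenate([a, b]), ["a"] * 15 + ["b"] * 10, test="welch_t"
            )
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            two_group_test([1.0, 2.0], ["a", "a"], test="mann_whitney")


def _trend_shuffle_oracle_p(table, n_shuffles=100_000, seed=0):
    """Literal label-shuffling permutation p for the trend statistic."""
    table = np.asarray(table)
    totals = table.sum(axis=0)
    scores = np.arange(1, table.shape[1] + 1, dtype=float)
    subj_scores = np.repeat(scores, totals.astype(int))
    A = int(table[0].sum())
    obs = _trend_statistic(table[0].astype(float), totals.astype(float), scores)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        pick = rng.permutation(len(subj_scores))[:A]
        a = np.array([
            np.sum(subj_scores[pick] == s) for s in scores
        ], dtype=float)
        if _trend_statistic(a, totals.astype(float), scores) >= obs - 1e-12:
            hits += 1
    return hits / n_shuffles


def _trend_exhaustive_oracle_p(table):
    """Exact permutation p by enumerating success subsets directly."""
    table = np.asarray(table)
    totals = table.sum(axis=0).astype(int)
    scores = np.arange(1, table.shape[1] + 1, dtype=float)
    obs = _trend_statistic(table[0].astype(float), totals.astype(float), scores)
    subj_scores = np.repeat(scores, totals)
    A = int(table[0].sum())
    hits = 0
    total = 0
    for idx in itertools.combinations(range(len(subj_scores)), A):
        a = np.array([np.sum(subj_scores[list(idx)] == s) for s in scores])
        if _trend_statistic(a.astype(float), totals.astype(float), scores) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestTrend:
    def test_equal_proportions_no_trend(self):
        stat, p = trend_test([[5, 5, 5], [5, 5, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_monotone_trend(self):
        stat, p = trend_test([[0, 5, 10], [10, 5, 0]])
        assert p < 0.001
        _, p_exact = trend_test([[0, 5, 10], [10, 5, 0]], method="exact")
        assert p_exact < 0.001

    def test_exact_matches_exhaustive_enumeration_small_tables(self):
        # every 2x3 table with total <= 12 and non-zero column totals
        count = 0
        for n1, n2, n3 in itertools.product(range(1, 6), repeat=3):
            if n1 + n2 + n3 > 8:
                continue
            for a1, a2, a3 in itertools.product(
                range(n1 + 1), range(n2 + 1), range(n3 + 1)
            ):
                A = a1 + a2 + a3
                if A == 0 or A == n1 + n2 + n3:
                    continue
                table = [[a1, a2, a3], [n1 - a1, n2 - a2, n3 - a3]]
                _, p = trend_test(table, method="exact")
                assert p == pytest.approx(
                    _trend_exhaustive_oracle_p(table), abs=1e-9
                ), table
                count += 1
        assert count > 100

    def test_exact_matches_shuffle_oracle(self):
        table = [[1, 2, 3], [9, 8, 7]]
        _, p = trend_test(table, method="exact")
        oracle = _trend_shuffle_oracle_p(table, n_shuffles=20_000, seed=1)
        # Monte-Carlo error ~ 3*sqrt(p(1-p)/20000)
        assert p == pytest.approx(oracle, abs=0.012)

    def test_zero_column_total_rejected(self):
        with pytest.raises(StatsError):
            trend_test([[1, 0, 3], [2, 0, 4]])

    def test_needs_three_categories(self):
        with pytest.raises(StatsError):
            trend_test([[1, 2], [3, 4]])


class TestQuadrants:
    def test_examples_and_boundary_rule(self):
        x = pd.Series([0.5, 0.0, -1.0, 2.0])
        y = pd.Series([0.5, 0.0, 1.0, -0.1])
        labels, counts = median_split_quadrants(x, y)
        assert list(labels) == ["RUQ", "LLQ", "LUQ", "RLQ"]
        assert counts.to_numpy().sum() == 4

    def test_counts_conserved(self, rng):
        x = pd.Series(rng.normal(size=500))
        y = pd.Series(rng.normal(size=500))
        _, counts = median_split_quadrants(x, y)
        assert counts.to_numpy().sum() == 500

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            median_split_quadrants(pd.Series([1.0]), pd.Series([1.0, 2.0]))


class TestTableOne:
    def test_reference_crosstab_percentages(self):
        clinical, labels = reference_crosstab()
        t1 = table_one(clinical, labels)
        pct = t1.attrs["percentages"]
        counts = t1.attrs["counts"]
        assert counts.loc["CMS1", "N"] == 305 and pct.loc["CMS1", "N"] == 13.6
        assert counts.loc["Total", "Stage III"] == 536
        assert pct.loc["Total", "Stage III"] == 36.1
        assert pct.loc["Total", "Metastatic"] == 34.0
        assert pct.loc["Total", "Primary"] == 66.0
        assert pct.loc["Total", "F"] == 47.4 and pct.loc["Total", "M"] == 52.6
        assert t1.attrs["denominators"]["F"] == 2249
        assert t1.attrs["denominators"]["Metastatic"] == 2249
        assert t1.attrs["denominators"]["Stage I"] == 1485

    def test_single_class_cohort_hundred_percent(self):
        df = pd.DataFrame(
            {"sex": ["F", "M"], "site_type": ["primary", "primary"],
             "stage": ["I", "II"]},
            index=["s1", "s2"],
        )
        labels = pd.Series(["CMS2", "CMS2"], index=df.index)
        t1 = table_one(ClinicalTable(df=df), labels)
        assert t1.attrs["percentages"].loc["CMS2", "N"] == 100.0

    def test_percentages_sum_within_rounding(self):
        clinical, labels = reference_crosstab()
        pct = table_one(clinical, labels).attrs["percentages"]
        class_rows = ["CMS1", "CMS2", "CMS3", "CMS4", "CMS-NA"]
        assert pct.loc[class_rows, "N"].sum() == pytest.approx(100.0, abs=0.1 * 5)
        stage_cols = [f"Stage {s}" for s in ("I", "II", "III", "IV", "NA")]
        assert pct.loc["Total", stage_cols].sum() == pytest.approx(100.0, abs=0.1 * 5)


class TestClinicalValidation:
    def test_negative_os_time_rejected(self):
        df = pd.DataFrame({"os_time": [-1.0], "os_event": [True]}, index=["s"])
        with pytest.raises(StatsError):
            ClinicalTable(df=df)

    def test_stage_on_metastatic_rejected(self):
        df = pd.DataFrame(
            {"site_type": ["metastatic"], "stage": ["II"]}, index=["s"]
        )
        with pytest.raises(StatsError):
            ClinicalTable(df=df)


def test_round_half_up():
    assert round_half_up(13.55, 1) == 13.6
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(9.6296, 1) == 9.6
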