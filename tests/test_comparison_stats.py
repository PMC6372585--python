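"""Repeated-measures ANOVA, post-hoc contrasts, correlations, group tests."""

import numpy as np
import pandas as pd
import pytest

from glomorph import (
    MeasurementTable,
    group_comparison,
    method_correlations,
    posthoc_contrasts,
    repeated_measures_anova,
)
from glomorph.comparison_stats import InsufficientDataError


def brute_force_rm_anova(x: np.ndarray):
    """Independent sums-of-squares oracle: explicit cell-by-cell loops."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_method = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subject = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_error = ss_total - ss_method - ss_subject
    f = (ss_method / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))
    return f, ss_method, ss_subject, ss_error, ss_total


def table_from_matrix(x: np.ndarray, methods=("TEM", "PSI", "THREE_D")) -> MeasurementTable:
    rows = [
        (f"u{i}", methods[j], float(x[i, j]))
        for i in range(x.shape[0])
        for j in range(x.shape[1])
    ]
    return MeasurementTable.from_long(rows)


class TestRepeatedMeasuresAnova:
    def test_identical_columns_give_f_zero(self, rng):
        col = rng.uniform(100, 1000, 8)
        x = np.column_stack([col, col, col])
        res = repeated_measures_anova(table_from_matrix(x))
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_df_structure_for_nine_units_three_methods(self, rng):
        x = rng.uniform(100, 1000, (9, 3))
        res = repeated_measures_anova(table_from_matrix(x))
        assert (res.df_between, res.df_error) == (2, 16)

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(2, 5))
            x = rng.uniform(10, 1000, (n, k))
            res = repeated_measures_anova(table_from_matrix(x, methods=[f"m{j}" for j in range(k)]))
            f, ssm, sss, sse, sst = brute_force_rm_anova(x)
            assert res.f_statistic == pytest.approx(f, abs=1e-10 * max(1, f))
            assert res.ss_method + res.ss_subject + res.ss_error == pytest.approx(sst, rel=1e-9)

    def test_matches_statsmodels_anovarm(self, rng):
        """Cross-check against the library implementation on a random table."""
        from statsmodels.stats.anova import AnovaRM

        x = rng.uniform(100, 1000, (8, 3))
        long = pd.DataFrame(
            [
                {"unit": i, "method": f"m{j}", "value": x[i, j]}
                for i in range(8)
                for j in range(3)
            ]
        )
        sm_res = AnovaRM(long, depvar="value", subject="unit", within=["method"]).fit()
        res = repeated_measures_anova(table_from_matrix(x, methods=("m0", "m1", "m2")))
        assert res.f_statistic == pytest.approx(float(sm_res.anova_table["F Value"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(sm_res.anova_table["Pr > F"].iloc[0]), abs=1e-12)

    def test_additive_table_flags_infinite_f(self):
        subject = np.arange(5, dtype=float)[:, None]
        method = np.array([[10.0, 20.0, 30.0]])
        x = subject + method  # zero interaction -> zero error variance
        res = repeated_measures_anova(table_from_matrix(x))
        assert res.infinite_f
        assert res.p_value == 0.0

    def test_insufficient_units_rejected(self):
        with pytest.raises(InsufficientDataError):
            repeated_measures_anova(table_from_matrix(np.array([[1.0, 2.0]])))

    def test_incomplete_units_dropped(self):
        rows = [
            ("u0", "TEM", 1.0), ("u0", "PSI", 2.0),
            ("u1", "TEM", 3.0), ("u1", "PSI", 4.0),
            ("u2", "TEM", 5.0),  # missing PSI -> dropped
        ]
        table = MeasurementTable.from_long(rows)
        assert table.n_units == 2
        assert table.n_dropped == 1


class TestPosthoc:
    def test_exact_thirty_percent_reduction(self, rng):
        a = rng.uniform(100, 1000, 10)
        x = np.column_stack([a, 0.7 * a])
        table = table_from_matrix(x, methods=("TEM", "PSI"))
        row = posthoc_contrasts(table).iloc[0]
        assert row.percent_difference == pytest.approx(-30.0)

    def test_identical_columns(self, rng):
        a = rng.uniform(100, 1000, 10)
        table = table_from_matrix(np.column_stack([a, a]), methods=("TEM", "PSI"))
        row = posthoc_contrasts(table).iloc[0]
        assert row.percent_difference == 0.0
        assert row.p_value == 1.0

    def test_percent_difference_antisymmetry(self, rng):
        """(1 + pct(A,B)/100)(1 + pct(B,A)/100) = 1."""
        x = rng.uniform(100, 1000, (10, 2))
        fwd = posthoc_contrasts(table_from_matrix(x, methods=("A", "B"))).iloc[0]
        rev = posthoc_contrasts(table_from_matrix(x[:, ::-1], methods=("B", "A"))).iloc[0]
        assert (1 + fwd.percent_difference / 100) * (1 + rev.percent_difference / 100) == pytest.approx(1.0)


class TestCorrelations:
    def test_perfect_linear_relations(self, rng):
        a = rng.uniform(100, 1000, 10)
        table = table_from_matrix(np.column_stack([a, 2 * a]), methods=("A", "B"))
        assert method_correlations(table).iloc[0].pearson_r == pytest.approx(1.0)
        table_neg = table_from_matrix(np.column_stack([a, -a + 2000]), methods=("A", "B"))
        assert method_correlations(table_neg).iloc[0].pearson_r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        table = table_from_matrix(np.column_stack([np.arange(5.0), np.full(5, 3.0)]), methods=("A", "B"))
        with pytest.raises(ValueError, match="variance"):
            method_correlations(table)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        res = group_comparison(vals, groups)
        assert res["p_value"] == pytest.approx(1.0)

    def test_widely_separated_groups(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)  # shifted by 10 SD
        res = group_comparison(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 10)
        assert res["test"] == "welch_t"
        assert res["p_value"] < 1e-6

    def test_three_groups_use_anova(self, rng):
        vals = rng.normal(0, 1, 15)
        res = group_comparison(vals, ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        assert res["test"] == "one_way_anova"

    def test_singleton_group_flagged_nan_sd(self):
        res = group_comparison([1.0, 2.0, 3.0], ["a", "a", "b"])
        assert np.isnan(res["groups"]["b"]["sd"])
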