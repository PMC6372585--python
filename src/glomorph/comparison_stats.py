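"""Method-comparison statistics for morphometry measurements.

Compares mesangial volume estimates obtained by several methods (TEM
planimetry, PSI point counting, 3D reconstruction) on the same units:
one-way within-subject (repeated-measures) ANOVA, post-hoc paired contrasts
with percent differences, pairwise Pearson correlations, and between-group
comparisons of morphometric summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METHODS = ("TEM", "PSI", "THREE_D")


class InsufficientDataError(ValueError):
    """Fewer than two complete units (or methods) available."""


@dataclass(frozen=True)
class MeasurementTable:
    """Complete-case units x methods measurement matrix.

    Built from long-format rows ``(unit_id, method, value)``; units lacking a
    value for any method are dropped listwise (with a logged count), so every
    retained unit has exactly one value per method.
    """

    data: pd.DataFrame  # index = unit_id, columns = methods
    n_dropped: int = 0

    @classmethod
    def from_long(cls, rows: pd.DataFrame | list[tuple]) -> "MeasurementTable":
        if not isinstance(rows, pd.DataFrame):
            rows = pd.DataFrame(rows, columns=["unit_id", "method", "value_um3"])
        wide = rows.pivot_table(index="unit_id", columns="method", values="value_um3", aggfunc="first")
        wide = wide[list(dict.fromkeys(rows["method"]))]  # keep first-appearance method order
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.info("dropped %d incomplete units (listwise deletion)", n_dropped)
        if (complete.values < 0).any():
            raise ValueError("measurement values must be non-negative")
        return cls(complete, n_dropped)

    @property
    def methods(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_units(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class AnovaResult:
    """One-way within-subject ANOVA summary."""

    f_statistic: float
    df_between: int
    df_error: int
    p_value: float
    grand_mean: float
    per_method_means: dict[str, float]
    ss_method: float
    ss_subject: float
    ss_error: float
    infinite_f: bool = False

    def summary(self) -> str:
        return (
            f"F({self.df_between}, {self.df_error}) = {self.f_statistic:.2f}, "
            f"p = {self.p_value:.4g}"
        )


def repeated_measures_anova(table: MeasurementTable) -> AnovaResult:
    """One-way repeated-measures ANOVA across methods.

    Standard within-subject decomposition for *n* units measured by each of
    *k* methods::

        SS_method  = n * sum_j (m_j - m)^2
        SS_subject = k * sum_i (m_i - m)^2
        SS_error   = SS_total - SS_method - SS_subject
        F = (SS_method / (k-1)) / (SS_error / ((k-1)(n-1)))

    with the p-value from ``F(k-1, (k-1)(n-1))``.  No sphericity correction
    is applied by default (the uncorrected F is what comparable analyses
    report); a zero error variance is flagged via ``infinite_f``.
    """
    x = table.data.values.astype(float)
    n, k = x.shape
    if k < 2 or n < 2:
        raise InsufficientDataError("need >= 2 methods and >= 2 complete units")
    grand = x.mean()
    method_means = x.mean(axis=0)
    unit_means = x.mean(axis=1)
    ss_method = n * float(((method_means - grand) ** 2).sum())
    ss_subject = k * float(((unit_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_method - ss_subject
    df_b, df_e = k - 1, (k - 1) * (n - 1)
    ms_method = ss_method / df_b
    ms_error = ss_error / df_e
    if ms_error <= 0:
        if ms_method <= 0:  # all columns identical and no subject scatter residual
            f = 0.0
            p = 1.0
            inf = False
        else:
            f = float("inf")
            p = 0.0
            inf = True
    else:
        f = ms_method / ms_error
        p = float(stats.f.sf(f, df_b, df_e))
        inf = False
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_b,
        df_error=df_e,
        p_value=p,
        grand_mean=float(grand),
        per_method_means=dict(zip(table.methods, method_means.astype(float))),
        ss_method=ss_method,
        ss_subject=ss_subject,
        ss_error=ss_error,
        infinite_f=inf,
    )


def posthoc_contrasts(table: MeasurementTable) -> pd.DataFrame:
    """Pairwise post-hoc contrasts between methods.

    For every ordered-unimportant pair (A, B): mean difference ``mean_B -
    mean_A``, percent difference ``100 * (mean_B - mean_A) / mean_A``, the
    paired t-test p-value on the within-unit differences, and the
    Bonferroni-adjusted p (times the number of pairs, capped at 1).
    """
    cols = table.methods
    n_pairs = len(cols) * (len(cols) - 1) // 2
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            va, vb = table.data[a].values, table.data[b].values
            mean_a, mean_b = float(va.mean()), float(vb.mean())
            if mean_a == 0:
                raise ZeroDivisionError(f"mean of {a} is zero; percent difference undefined")
            diff = vb - va
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.ttest_rel(vb, va).pvalue)
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "mean_difference": mean_b - mean_a,
                    "percent_difference": 100.0 * (mean_b - mean_a) / mean_a,
                    "p_value": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return pd.DataFrame(rows)


def method_correlations(table: MeasurementTable) -> pd.DataFrame:
    """Pairwise Pearson correlation between method columns."""
    if table.n_units < 3:
        raise InsufficientDataError("need >= 3 complete units for correlations")
    cols = table.methods
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            va, vb = table.data[a].values, table.data[b].values
            if va.std() == 0 or vb.std() == 0:
                raise ValueError(f"zero variance in {a if va.std() == 0 else b}; correlation undefined")
            r = float(stats.pearsonr(va, vb).statistic)
            rows.append({"method_a": a, "method_b": b, "pearson_r": r})
    return pd.DataFrame(rows)


def group_comparison(values, groups) -> dict:
    """Compare a morphometric quantity between groups.

    Per-group mean and SD, plus a Welch two-sample t-test for two groups or a
    one-way ANOVA for three or more.  Groups of size one get ``sd = nan`` and
    are flagged.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    if df["group"].nunique() < 2:
        raise InsufficientDataError("need at least 2 groups")
    per_group = {}
    singleton = []
    samples = []
    for g, sub in df.groupby("group", sort=False):
        v = sub["value"].values
        per_group[g] = {"n": len(v), "mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan")}
        if len(v) == 1:
            singleton.append(g)
        samples.append(v)
    if singleton:
        logger.warning("groups with a single observation (SD undefined): %s", singleton)
    if len(samples) == 2:
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        test = {"test": "welch_t", "statistic": float(res.statistic), "p_value": float(res.pvalue)}
        if np.allclose(samples[0].mean(), samples[1].mean()) and np.isnan(res.pvalue):
            test["p_value"] = 1.0
    else:
        res = stats.f_oneway(*samples)
        test = {"test": "one_way_anova", "statistic": float(res.statistic), "p_value": float(res.pvalue)}
    return {"groups": per_group, **test}


def comparison_report(table: MeasurementTable) -> str:
    """Plain-text summary: ANOVA line, pairwise percents, correlations."""
    anova = repeated_measures_anova(table)
    posthoc = posthoc_contrasts(table)
    corr = method_correlations(table)
    lines = [
        f"Within-subject ANOVA across methods: {anova.summary()} "
        f"(n = {table.n_units} units, {len(table.methods)} methods)",
    ]
    for _, row in posthoc.iterrows():
        lines.append(
            f"  {row.method_b} vs {row.method_a}: {row.percent_difference:+.1f}% "
            f"(p = {row.p_value:.4g}, Bonferroni p = {row.p_bonferroni:.4g})"
        )
    for _, row in corr.iterrows():
        lines.append(f"  r({row.method_a}, {row.method_b}) = {row.pearson_r:.2f}")
    return "\n".join(lines)
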