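"""Statistical tests and replicate-level aggregation for figure readouts.

Covers two-tailed paired/unpaired t tests (pooled-variance Student by
default, Welch behind a flag), one-way ANOVA with Tukey's HSD post hoc,
and the replicate-first aggregation pattern: per-replicate summary
statistics (mean form factor, % blebbing, % foci-positive) are computed
first and condition-level tests run on those replicate values, since
pooling individual cells across replicates would pseudo-replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "stars",
    "t_test",
    "anova_tukey",
    "max_studentized_range",
    "tukey_critical_q",
    "aggregate_replicates",
    "compare_conditions",
]


def stars(p: float) -> str:
    """Significance stars: ns > 0.05, * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001."""
    if np.isnan(p):
        return "na"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    pvalue: float
    comparison: str = ""
    valid: bool = True
    note: str = ""

    @property
    def stars(self) -> str:
        return stars(self.pvalue)


def t_test(x, y, paired: bool = False, welch: bool = False) -> TestResult:
    """Two-tailed two-sample t test (Student pooled-variance by default).

    Degenerate inputs with zero variance in both groups return p = 1 when
    the means are equal and p = 0 otherwise, rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    with warnings.catch_warnings():
        # near-identical groups trip scipy's precision warning; the
        # degenerate zero-variance case is resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if len(x) != len(y):
                raise ValueError("paired test requires equal-length groups")
            res = stats.ttest_rel(x, y)
            name, df = "paired t test", float(len(x) - 1)
        else:
            res = stats.ttest_ind(x, y, equal_var=not welch)
            name = "Welch t test" if welch else "unpaired t test"
            df = float(res.df)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):  # zero variance everywhere
        same = np.isclose(np.mean(x), np.mean(y))
        stat = 0.0 if same else np.sign(np.mean(x) - np.mean(y)) * np.inf
        p = 1.0 if same else 0.0
    return TestResult(name=name, statistic=stat, df=df, pvalue=p)


def anova_tukey(groups: dict[str, np.ndarray]) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus all-pairs Tukey HSD adjusted p-values.

    ``groups`` maps condition label to its value vector (≥ 3 groups of
    ≥ 2 values each). If every value is identical the F statistic is
    undefined; an invalid result is returned instead of raising.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups (use t_test for 2)")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    n_total = sum(len(a) for a in arrays)
    df_resid = float(n_total - len(arrays))
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        bad = TestResult(name="one-way ANOVA", statistic=np.nan, df=df_resid,
                         pvalue=np.nan, valid=False,
                         note="zero variance in every group: F undefined")
        return bad, []
    f_stat, f_p = stats.f_oneway(*arrays)
    anova = TestResult(name="one-way ANOVA", statistic=float(f_stat),
                       df=df_resid, pvalue=float(f_p))
    hsd = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pairwise.append(TestResult(
                name="Tukey HSD", statistic=float(hsd.statistic[i, j]),
                df=df_resid, pvalue=float(hsd.pvalue[i, j]),
                comparison=f"{labels[i]} vs {labels[j]}"))
    return anova, pairwise


def max_studentized_range(data: np.ndarray) -> np.ndarray:
    """Per-replicate maximum studentized range statistic, vectorized.

    ``data`` has shape (replicates, k groups, n per group), balanced.
    Returns q = (max group mean - min group mean) / sqrt(MSE / n) per
    replicate. For a single replicate, ``q > tukey_critical_q(alpha, k,
    k*(n-1))`` is exactly equivalent to the smallest Tukey-adjusted
    pairwise p-value being below alpha, which makes large family-wise
    error simulations tractable.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected (replicates, groups, n) array")
    means = data.mean(axis=2)
    mse = data.var(axis=2, ddof=1).mean(axis=1)
    n = data.shape[2]
    return (means.max(axis=1) - means.min(axis=1)) / np.sqrt(mse / n)


def tukey_critical_q(alpha: float, k: int, df: float) -> float:
    """Critical value of the studentized range for k groups and df error dof."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def aggregate_replicates(measurements: pd.DataFrame, value_col: str,
                         condition_col: str = "condition",
                         replicate_col: str = "replicate",
                         statistic=np.mean) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-first aggregation: per-replicate statistic, then per-condition.

    Returns ``(per_replicate, per_condition)``; the per-condition table
    carries mean ± SD over replicate-level values (SD is NaN for a single
    replicate). ``statistic`` is any reduction of a value vector, e.g.
    ``np.mean`` or :func:`nepheno.morphometry.percent_blebbing`.
    """
    if measurements.empty:
        raise ValueError("no measurements")
    rep_rows = []
    for (cond, rep), sub in measurements.groupby([condition_col, replicate_col], sort=True):
        rep_rows.append({condition_col: cond, replicate_col: rep,
                         "n": len(sub), "value": float(statistic(sub[value_col].to_numpy()))})
    per_rep = pd.DataFrame(rep_rows)
    cond_rows = []
    for cond, sub in per_rep.groupby(condition_col, sort=True):
        vals = sub["value"].to_numpy()
        cond_rows.append({
            condition_col: cond, "n_replicates": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
    return per_rep, pd.DataFrame(cond_rows)


def compare_conditions(per_replicate: pd.DataFrame, condition_col: str = "condition",
                       paired: bool = False, welch: bool = False) -> TestResult:
    """Two-condition test on replicate-level values (the declared test unit)."""
    conds = sorted(per_replicate[condition_col].unique())
    if len(conds) != 2:
        raise ValueError("compare_conditions expects exactly 2 conditions")
    x = per_replicate.loc[per_replicate[condition_col] == conds[0], "value"].to_numpy()
    y = per_replicate.loc[per_replicate[condition_col] == conds[1], "value"].to_numpy()
    res = t_test(x, y, paired=paired, welch=welch)
    res.comparison = f"{conds[0]} vs {conds[1]}"
    return res
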