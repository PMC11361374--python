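"""Differential-expression filtering on gene-level count matrices.

The defined computations are median-of-ratios size-factor normalization,
Benjamini-Hochberg adjustment of per-gene p-values, and subsetting of
significantly up-/down-regulated genes at strict thresholds
(padj < 0.001, |log2FC| > 2 by default). The per-gene test itself is
pluggable: any externally computed (gene, log2fc, pvalue) table can feed
:func:`classify_de`, and :func:`per_gene_test` provides a simple built-in
default (t test on log-normalized counts) for synthetic data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "per_gene_test",
    "bh_adjust",
    "classify_de",
    "de_subset",
]

PADJ_MAX_DEFAULT = 0.001
LFC_MIN_DEFAULT = 2.0


def _as_count_frame(counts) -> pd.DataFrame:
    df = pd.DataFrame(counts)
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return df


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors (genes × samples in, one factor per sample).

    For each sample j the factor is the median over usable genes of
    counts[g, j] / geomean_g, where geomean_g is the geometric mean of
    gene g across samples; genes with a zero count in any sample
    (geomean 0) are unusable.
    """
    df = _as_count_frame(counts)
    arr = df.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has all-positive counts")
    log_arr = np.log(arr[usable])
    log_geomean = log_arr.mean(axis=1)
    factors = np.exp(np.median(log_arr - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def per_gene_test(counts, sf: pd.Series, groups: pd.Series,
                  pseudocount: float = 0.5) -> pd.DataFrame:
    """Built-in per-gene test: log2FC of normalized means + t test.

    Counts are divided by the sample size factors; the fold change is
    log2((mean2 + pseudocount)/(mean1 + pseudocount)) for group 2 vs
    group 1 (groups in sorted label order), and the p-value is a
    two-sided pooled-variance t test on log2(normalized + pseudocount)
    per gene. This is a pluggable stand-in, not a negative-binomial
    Wald test; precomputed tables can be used instead.
    """
    df = _as_count_frame(counts)
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    cols1 = groups.index[groups == levels[0]]
    cols2 = groups.index[groups == levels[1]]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs >= 2 samples")

    norm = df / sf.reindex(df.columns)
    m1 = norm[cols1].mean(axis=1)
    m2 = norm[cols2].mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    logn = np.log2(norm + pseudocount)
    with warnings.catch_warnings():
        # genes with identical counts in both groups trip scipy's
        # catastrophic-cancellation warning; their p is set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(logn[cols2].to_numpy(), logn[cols1].to_numpy(),
                              axis=1, equal_var=True)
    pvalue = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # zero-variance genes
    return pd.DataFrame({
        "gene": df.index,
        "log2fc": log2fc.to_numpy(),
        "pvalue": pvalue,
    }).reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    padj_(i) = min_{k >= i} p_(k) * m / k over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(results: pd.DataFrame, padj_max: float = PADJ_MAX_DEFAULT,
                lfc_min: float = LFC_MIN_DEFAULT) -> pd.DataFrame:
    """Add BH-adjusted p-values and an up/down/ns call to a results table.

    ``results`` needs columns ``gene, log2fc, pvalue``; the call uses
    strict inequalities: up when padj < padj_max and log2fc > lfc_min,
    down when padj < padj_max and log2fc < -lfc_min, else ns.
    """
    for col in ("gene", "log2fc", "pvalue"):
        if col not in results.columns:
            raise ValueError(f"results table lacks column {col!r}")
    out = results.copy()
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    sig = out["padj"] < padj_max
    out["call"] = np.where(sig & (out["log2fc"] > lfc_min), "up",
                           np.where(sig & (out["log2fc"] < -lfc_min), "down", "ns"))
    return out


def de_subset(results: pd.DataFrame, padj_max: float = PADJ_MAX_DEFAULT,
              lfc_min: float = LFC_MIN_DEFAULT) -> tuple[list, list]:
    """Up- and down-regulated gene lists at strict thresholds.

    A gene with padj exactly equal to ``padj_max`` or |log2fc| exactly
    equal to ``lfc_min`` is excluded ("less than" / "greater than").
    """
    if "padj" not in results.columns:
        results = classify_de(results, padj_max=padj_max, lfc_min=lfc_min)
    sig = results["padj"] < padj_max
    up = results.loc[sig & (results["log2fc"] > lfc_min), "gene"].tolist()
    down = results.loc[sig & (results["log2fc"] < -lfc_min), "gene"].tolist()
    return up, down
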