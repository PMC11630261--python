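"""Expression strata, mark/expression cross-tabulation, rank tests, random
gene panels and expression breadth.

FPKM strata follow the usual plant convention: high (>10), mid (1,10],
low (0,1], none (=0); a condition's per-gene value is the mean over its
replicates.  Marked-versus-all comparisons use the two-sided Wilcoxon
rank-sum test, exact for small groups without ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import condition_of_sample
from .peak_annotation import MarkedGeneSet

CATEGORIES = ("high", "mid", "low", "none")


def condition_means(expr: pd.DataFrame, condition: str) -> pd.Series:
    """Mean FPKM per gene over the replicate columns of one condition."""
    cols = [c for c in expr.columns if condition_of_sample(c) == condition]
    if not cols:
        raise ValueError(f"no samples for condition {condition!r}")
    return expr[cols].mean(axis=1)


def categorize_expression(expr: pd.DataFrame, condition: str) -> pd.Series:
    """Total, exclusive stratum per gene: none/low/mid/high.

    Boundary closure: low = (0,1], mid = (1,10], high = (10,inf) — a gene at
    exactly 1 FPKM is low, at exactly 10 mid.
    """
    v = condition_means(expr, condition)
    out = pd.Series("none", index=v.index, dtype=object, name="category")
    out[(v > 0) & (v <= 1)] = "low"
    out[(v > 1) & (v <= 10)] = "mid"
    out[v > 10] = "high"
    return out


def mark_by_category(marked: MarkedGeneSet, cats: pd.Series) -> pd.DataFrame:
    """Counts and fractions of a marked gene set across expression strata."""
    if len(marked) == 0:
        raise ValueError("empty marked gene set: fractions undefined")
    unknown = set(marked.genes) - set(cats.index)
    if unknown:
        raise KeyError(f"marked genes missing from category map: {sorted(unknown)[:5]}")
    counts = {c: 0 for c in CATEGORIES}
    for g in marked.genes:
        counts[cats[g]] += 1
    n = len(marked)
    return pd.DataFrame({
        "count": pd.Series(counts),
        "fraction": pd.Series({c: k / n for c, k in counts.items()}),
    }).loc[list(CATEGORIES)]


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float
    method: str


def rank_compare(group_a, group_b, mode: str = "auto") -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    ``mode='auto'`` uses the exact null distribution when both groups have
    n <= 20 and the pooled values carry no ties, else the tie-corrected
    normal approximation.  All-tied inputs give p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both groups; p = 1")
        return RankTestResult(a.size * b.size / 2, 1.0,
                              float(np.median(a)), float(np.median(b)), "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact" or (mode == "auto" and not has_ties and max(a.size, b.size) <= 20):
        method = "exact"
    elif mode in ("auto", "normal"):
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                          float(np.median(a)), float(np.median(b)), method)


def sample_random_genes(all_genes, n: int = 10_000, seed: int = 0) -> frozenset[str]:
    """Seeded uniform sample of gene ids without replacement."""
    ids = sorted(all_genes) if not isinstance(all_genes, (list, tuple)) else list(all_genes)
    rng = np.random.default_rng(seed)
    if n >= len(ids):
        if n > len(ids):
            warnings.warn(f"requested {n} genes from {len(ids)}; returning all")
        return frozenset(ids)
    picked = rng.choice(len(ids), size=n, replace=False)
    return frozenset(ids[i] for i in picked)


def expression_breadth(expr: pd.DataFrame, breadth_threshold: float = 1.0) -> pd.Series:
    """Fraction of samples in which each gene is expressed above threshold."""
    if expr.shape[1] < 2:
        raise ValueError("breadth needs at least 2 samples")
    return (expr >= breadth_threshold).mean(axis=1).rename("breadth")


def tau_specificity(expr: pd.DataFrame) -> pd.Series:
    """Tau tissue-specificity index: 0 = uniform, 1 = single-sample.

    Offered as the alternative breadth-style summary; computed on log2(x+1)
    per the usual convention.  Genes silent everywhere get tau = 0.
    """
    x = np.log2(expr.to_numpy(dtype=float) + 1.0)
    xmax = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1 - x / xmax[:, None]).sum(axis=1) / (n - 1)
    tau[~np.isfinite(tau)] = 0.0
    return pd.Series(tau, index=expr.index, name="tau")
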