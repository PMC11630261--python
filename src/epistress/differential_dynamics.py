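"""Control-versus-stress contrasts: differential expression, per-gene mark
gain/loss, expression-concordance classes, promoter enrichment of changed
peaks, fold-change correlations, interval variability and the differential
metabolite filter.

The gain/loss call is presence-based with a Jaccard floor: a gene marked in
both conditions is *stable* only when the basepair Jaccard of its peak
coverage (within the promoter-plus-body window) is at least
``min_jaccard_stable``; below the floor the sign of the pseudocounted
occupancy log-ratio decides between gain and loss, so wholesale peak
replacement is not mistaken for stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _intervals as iv
from .genome_model import FeatureIndex, GeneModel, GenomeLayout, PeakSet

STATUSES = ("gain", "loss", "stable", "absent")

#: The six concordant (mark change, expression change) pairings.
CONCORDANT_CLASSES = (
    ("H3K4me3", "gain", "up"),
    ("H3K4me3", "loss", "down"),
    ("H3K9ac", "gain", "up"),
    ("H3K9ac", "loss", "down"),
    ("H3K27me3", "gain", "down"),
    ("H3K27me3", "loss", "up"),
)


# ---------------------------------------------------------------------------
# differential expression

def simple_de(expr: pd.DataFrame, cond_a: str = "CK", cond_b: str = "NaCl",
              pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-sample t on log2(FPKM + c) with BH-adjusted p-values.

    log2FC is computed on pseudocounted condition means (b over a).  Genes
    with zero variance in both groups get p = 1 when the means agree and
    p = 0 when they differ (the noise-free limit).
    """
    from .io_formats import condition_of_sample
    cols_a = [c for c in expr.columns if condition_of_sample(c) == cond_a]
    cols_b = [c for c in expr.columns if condition_of_sample(c) == cond_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >=2 replicates per condition")
    A = np.log2(expr[cols_a].to_numpy(dtype=float) + pseudocount)
    B = np.log2(expr[cols_b].to_numpy(dtype=float) + pseudocount)
    mean_a = expr[cols_a].mean(axis=1).to_numpy()
    mean_b = expr[cols_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=True)
    degenerate = ~np.isfinite(p)
    same = np.isclose(A.mean(axis=1), B.mean(axis=1))
    p = np.where(degenerate & same, 1.0, p)
    p = np.where(degenerate & ~same, 0.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": log2fc, "pvalue": p, "fdr": fdr}, index=expr.index)


def call_de(de: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05):
    """Up/down DEG sets: |log2FC| >= lfc_min (boundary in) and FDR < fdr_max
    (boundary out)."""
    sig = de["fdr"] < fdr_max
    up = frozenset(de.index[sig & (de["log2fc"] >= lfc_min)])
    down = frozenset(de.index[sig & (de["log2fc"] <= -lfc_min)])
    return up, down


# ---------------------------------------------------------------------------
# mark dynamics

def _window_overlap(merged: dict, g: GeneModel, layout: GenomeLayout,
                    promoter_window: int) -> tuple[int, iv.IntervalArrays]:
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))
    s, e = merged.get(g.chrom, empty)
    ws, we = g.gene_window(promoter_window, layout.length(g.chrom))
    si, ei = iv.intersect(s, e, np.array([ws], np.int64), np.array([we], np.int64))
    return iv.total_bp(si, ei), (si, ei)


def mark_gain_loss(
    peaks_ck: PeakSet,
    peaks_nacl: PeakSet,
    genes: list[GeneModel],
    layout: GenomeLayout,
    promoter_window: int = 2000,
    min_jaccard_stable: float = 0.25,
    pseudocount_bp: float = 100.0,
) -> pd.DataFrame:
    """Per-gene status (gain/loss/stable/absent) and occupancy log-ratio.

    Occupancy is the summed peak bp overlapping the promoter-plus-body
    window; the log-ratio is log2((bp_NaCl + c) / (bp_CK + c)).
    """
    if peaks_ck.mark != peaks_nacl.mark:
        raise ValueError(f"mark mismatch: {peaks_ck.mark} vs {peaks_nacl.mark}")
    m_ck = peaks_ck.by_chrom(merged=True)
    m_na = peaks_nacl.by_chrom(merged=True)
    rows = []
    for g in genes:
        bp_ck, (s1, e1) = _window_overlap(m_ck, g, layout, promoter_window)
        bp_na, (s2, e2) = _window_overlap(m_na, g, layout, promoter_window)
        marked_ck, marked_na = bp_ck > 0, bp_na > 0
        ratio = float(np.log2((bp_na + pseudocount_bp) / (bp_ck + pseudocount_bp)))
        if not marked_ck and not marked_na:
            status = "absent"
        elif not marked_ck:
            status = "gain"
        elif not marked_na:
            status = "loss"
        else:
            si, ei = iv.intersect(s1, e1, s2, e2)
            inter = iv.total_bp(si, ei)
            union = bp_ck + bp_na - inter
            jac = inter / union if union else 0.0
            if jac >= min_jaccard_stable:
                status = "stable"
            elif ratio > 0:
                status = "gain"
            elif ratio < 0:
                status = "loss"
            else:
                status = "stable"
        rows.append({"gene": g.gene_id, "status": status, "log_ratio": ratio,
                     "bp_ck": bp_ck, "bp_nacl": bp_na})
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class ConcordanceReport:
    """The six concordant class memberships plus DEG coverage by any class."""

    classes: dict[str, frozenset[str]]
    n_up: int
    n_down: int
    covered_up: frozenset[str]
    covered_down: frozenset[str]

    @property
    def up_coverage(self) -> float:
        return len(self.covered_up) / self.n_up if self.n_up else np.nan

    @property
    def down_coverage(self) -> float:
        return len(self.covered_down) / self.n_down if self.n_down else np.nan


def concordance(de_up: frozenset, de_down: frozenset,
                dynamics: dict[str, pd.DataFrame]) -> ConcordanceReport:
    """Intersect DEG sets with per-mark gain/loss sets into the six classes."""
    classes = {}
    for mark, change, direction in CONCORDANT_CLASSES:
        dyn = dynamics[mark]
        changed = frozenset(dyn.index[dyn["status"] == change])
        degs = de_up if direction == "up" else de_down
        classes[f"{mark}-{change}/{direction}"] = changed & degs
    covered_up = frozenset().union(
        *(v for k, v in classes.items() if k.endswith("/up")))
    covered_down = frozenset().union(
        *(v for k, v in classes.items() if k.endswith("/down")))
    return ConcordanceReport(classes=classes, n_up=len(de_up), n_down=len(de_down),
                             covered_up=covered_up, covered_down=covered_down)


def condition_unique_peaks(peaks_a: PeakSet, peaks_b: PeakSet) -> PeakSet:
    """Peaks of A with zero bp overlap against B's merged set ('changed'
    peaks private to A's condition)."""
    b_by = peaks_b.by_chrom(merged=True)
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))
    kept = [p for p in peaks_a
            if not iv.overlaps_point_set(*b_by.get(p.chrom, empty), p.start, p.end)]
    return PeakSet(mark=peaks_a.mark, condition=peaks_a.condition, intervals=kept)


@dataclass
class PromoterRate:
    n_changed_peaks: int
    peak_rate: float | None       # promoter-anchored changed peaks / changed peaks
    gene_rate: float | None       # class genes with a promoter-anchored changed peak


def promoter_rate(
    class_genes: frozenset[str],
    changed_peaks: PeakSet,
    index: FeatureIndex,
    genes: list[GeneModel],
    promoter_window: int = 2000,
) -> PromoterRate:
    """Promoter share of condition-private peaks over a concordance class.

    Both granularities are reported: the fraction of changed peaks anchored
    in promoters, and the fraction of class genes carrying at least one
    promoter-anchored changed peak.  Zero changed peaks gives missing rates.
    """
    layout = index.layout
    gene_models = {g.gene_id: g for g in genes}
    relevant = []
    promoter_hit_genes = set()
    for p in changed_peaks:
        for gid in class_genes:
            g = gene_models.get(gid)
            if g is None or g.chrom != p.chrom:
                continue
            ws, we = g.gene_window(promoter_window, layout.length(g.chrom))
            if p.start < we and p.end > ws:
                relevant.append(p)
                if index.classify(p.chrom, p.anchor) == "promoter":
                    promoter_hit_genes.add(gid)
                break
    if not relevant:
        return PromoterRate(0, None, None)
    n_prom = sum(1 for p in relevant if index.classify(p.chrom, p.anchor) == "promoter")
    gene_rate = len(promoter_hit_genes) / len(class_genes) if class_genes else None
    return PromoterRate(len(relevant), n_prom / len(relevant), gene_rate)


# ---------------------------------------------------------------------------
# correlations & variability

def fc_correlation(mark_ratios: dict[str, pd.Series], expr_lfc: pd.Series,
                   method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlations among mark log-ratios and the expression log2FC.

    Every mark-expression and mark-mark pair is computed over the genes with
    both values finite; constant vectors give missing r.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    series = dict(mark_ratios)
    series["expression"] = expr_lfc
    names = list(series)
    rows = []
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            joined = pd.concat([series[x], series[y]], axis=1, join="inner").dropna()
            joined = joined[np.isfinite(joined).all(axis=1)]
            n = len(joined)
            if n < 3 or joined.iloc[:, 0].nunique() == 1 or joined.iloc[:, 1].nunique() == 1:
                rows.append({"var_a": x, "var_b": y, "r": np.nan, "pvalue": np.nan, "n": n})
                continue
            fn = stats.pearsonr if method == "pearson" else stats.spearmanr
            r, p = fn(joined.iloc[:, 0], joined.iloc[:, 1])
            rows.append({"var_a": x, "var_b": y, "r": float(r), "pvalue": float(p), "n": n})
    return pd.DataFrame(rows)


def variability_score(peaks_a: PeakSet, peaks_b: PeakSet) -> float:
    """One minus the basepair Jaccard of the two merged peak sets.

    Identical sets score 0, disjoint sets 1; two empty sets score 0 by
    convention (flagged with a warning).
    """
    jac, _, union = iv.jaccard(peaks_a.by_chrom(merged=True),
                               peaks_b.by_chrom(merged=True))
    if union == 0:
        warnings.warn("both peak sets empty: variability reported as 0")
        return 0.0
    return 1.0 - jac


# ---------------------------------------------------------------------------
# metabolites

#: Threshold presets for the differential-metabolite filter.
METABOLITE_FILTERS = {
    "results": {"vip_min": 1.0, "fc_up": 1.5, "fc_down": 0.667, "p_max": 0.05},
    "strict": {"vip_min": 1.0, "fc_up": 2.0, "fc_down": 0.5, "p_max": 0.05},
}


def filter_metabolites(tab: pd.DataFrame, vip_min: float = 1.0, fc_up: float = 1.5,
                       fc_down: float = 0.667, p_max: float = 0.05) -> dict:
    """Differential metabolites per ion mode.

    up: VIP > vip_min and FC > fc_up and p < p_max;
    down: VIP > vip_min and FC < fc_down and p < p_max.  All gates strict.
    """
    out = {}
    for mode in ("pos", "neg"):
        sub = tab[tab["ion_mode"] == mode]
        gate = (sub["vip"] > vip_min) & (sub["pvalue"] < p_max)
        up = frozenset(sub.index[gate & (sub["fc"] > fc_up)])
        down = frozenset(sub.index[gate & (sub["fc"] < fc_down)])
        out[mode] = (up, down)
    return out
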