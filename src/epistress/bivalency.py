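"""Bivalent-domain calling from co-occurring antagonistic marks, reciprocal
reChIP validation, and a permutation null for the co-occurrence.

A bivalent domain is a maximal run of bases carried by *both* marks
(intersection semantics): merged connected components of pairwise A-B peak
intersections.  Sequential-ChIP (reChIP) peak sets in the two antibody
orders provide the wet-lab cross-check: a domain is supported when both
directions overlap it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _intervals as iv
from .genome_model import GenomeLayout, GenomicInterval, PeakSet
from .peak_annotation import marked_genes


@dataclass
class BivalentDomainSet:
    mark_pair: tuple[str, str]
    domains: list[GenomicInterval]
    frac_peaks_a: float
    frac_peaks_b: float
    n_peaks_a_involved: int
    n_peaks_b_involved: int
    genes: frozenset[str]

    def __len__(self):
        return len(self.domains)

    def by_chrom(self) -> dict[str, iv.IntervalArrays]:
        out: dict[str, list] = {}
        for d in self.domains:
            out.setdefault(d.chrom, []).append((d.start, d.end))
        return {c: iv.as_arrays(v) for c, v in out.items()}

    @property
    def total_bp(self) -> int:
        return sum(len(d) for d in self.domains)


@dataclass
class RechipValidation:
    n_domains: int
    frac_both: float
    frac_ab: float
    frac_ba: float
    supported_bp_fraction: float
    supported_gene_fraction: float

    def __post_init__(self):
        if self.n_domains and self.frac_both > min(self.frac_ab, self.frac_ba) + 1e-12:
            raise ValueError("both-direction support cannot exceed either direction")


def call_bivalent(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    genes=None,
    layout: GenomeLayout | None = None,
    min_overlap_bp: int = 1,
    promoter_window: int = 2000,
    extent: str = "intersection",
) -> BivalentDomainSet:
    """Call bivalent domains where the two marks' peaks co-occur.

    Pairwise A-B intersections of at least ``min_overlap_bp`` are merged into
    connected components.  A peak is *involved* when it contributes to at
    least one domain; the per-mark involved fractions quantify how much of
    each modification participates in the bivalent compartment.  With
    ``extent='union'`` each component is widened to the union of the
    contributing peaks.
    """
    if peaks_a.mark == peaks_b.mark:
        raise ValueError("bivalency requires two distinct marks")
    a_by = peaks_a.by_chrom(merged=True)
    b_by = peaks_b.by_chrom(merged=True)
    domains: list[GenomicInterval] = []
    dom_by_chrom: dict[str, iv.IntervalArrays] = {}
    for chrom in sorted(set(a_by) & set(b_by)):
        sa, ea = a_by[chrom]
        sb, eb = b_by[chrom]
        si, ei = iv.intersect(sa, ea, sb, eb)
        keep = (ei - si) >= min_overlap_bp
        si, ei = si[keep], ei[keep]
        if si.size == 0:
            continue
        si, ei = iv.merge(si, ei)
        if extent == "union":
            ws, we = [], []
            for s, e in zip(si, ei):
                ia = int(np.searchsorted(sa, s, side="right")) - 1
                ib = int(np.searchsorted(sb, s, side="right")) - 1
                ws.append(min(sa[max(ia, 0)], sb[max(ib, 0)]))
                we.append(max(ea[max(ia, 0)], eb[max(ib, 0)]))
            si, ei = iv.merge(np.array(ws, np.int64), np.array(we, np.int64))
        dom_by_chrom[chrom] = (si, ei)
        for s, e in zip(si, ei):
            domains.append(GenomicInterval(chrom, int(s), int(e)))

    def involved(peaks: PeakSet) -> int:
        n = 0
        for p in peaks:
            se = dom_by_chrom.get(p.chrom)
            if se is not None and iv.overlaps_point_set(se[0], se[1], p.start, p.end):
                n += 1
        return n

    n_a = involved(peaks_a)
    n_b = involved(peaks_b)
    covered = frozenset()
    if genes is not None and layout is not None and domains:
        dom_set = PeakSet(mark=peaks_a.mark, condition=peaks_a.condition,
                          intervals=domains)
        covered = marked_genes(dom_set, genes, layout, promoter_window).genes
    return BivalentDomainSet(
        mark_pair=(peaks_a.mark, peaks_b.mark),
        domains=sorted(domains, key=lambda d: (d.chrom, d.start)),
        frac_peaks_a=n_a / len(peaks_a) if len(peaks_a) else 0.0,
        frac_peaks_b=n_b / len(peaks_b) if len(peaks_b) else 0.0,
        n_peaks_a_involved=n_a,
        n_peaks_b_involved=n_b,
        genes=covered,
    )


def validate_rechip(
    domains: BivalentDomainSet,
    rechip_ab: PeakSet,
    rechip_ba: PeakSet,
    min_overlap_bp: int = 1,
    genes=None,
    layout: GenomeLayout | None = None,
    promoter_window: int = 2000,
) -> RechipValidation:
    """Fraction of domains overlapped by both reChIP directions.

    Support is reported at three granularities — per domain, per base and
    per covered gene — because a 'fraction overlapping' can reasonably mean
    any of the three.
    """
    ab = rechip_ab.by_chrom(merged=True)
    ba = rechip_ba.by_chrom(merged=True)
    n = len(domains)
    if n == 0:
        return RechipValidation(0, 0.0, 0.0, 0.0, 0.0, 0.0)
    hit_ab = hit_ba = hit_both = 0
    bp_both = 0
    empty = (np.empty(0, np.int64), np.empty(0, np.int64))
    supported = []
    for d in domains.domains:
        sab, eab = ab.get(d.chrom, empty)
        sba, eba = ba.get(d.chrom, empty)
        o_ab = iv.overlap_bp_with(sab, eab, d.start, d.end) >= min_overlap_bp
        o_ba = iv.overlap_bp_with(sba, eba, d.start, d.end) >= min_overlap_bp
        hit_ab += o_ab
        hit_ba += o_ba
        if o_ab and o_ba:
            hit_both += 1
            bp_both += len(d)
            supported.append(d)
    total_bp = domains.total_bp
    gene_frac = 0.0
    if genes is not None and layout is not None and domains.genes:
        if supported:
            sup = PeakSet(mark=domains.mark_pair[0], condition="other", intervals=supported)
            covered = marked_genes(sup, genes, layout, promoter_window).genes
            gene_frac = len(covered & domains.genes) / len(domains.genes)
    return RechipValidation(
        n_domains=n,
        frac_both=hit_both / n,
        frac_ab=hit_ab / n,
        frac_ba=hit_ba / n,
        supported_bp_fraction=bp_both / total_bp if total_bp else 0.0,
        supported_gene_fraction=gene_frac,
    )


def permutation_null(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    layout: GenomeLayout,
    n_perm: int = 200,
    seed: int = 0,
    min_overlap_bp: int = 1,
) -> tuple[int, float]:
    """Empirical p-value for the observed bivalent-domain count.

    B's intervals are placed uniformly at random within their chromosomes
    (lengths preserved) and the domain count recomputed; the add-one
    estimator p = (1 + #{perm >= obs}) / (n_perm + 1) never returns zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a_by = peaks_a.by_chrom(merged=True)

    def count_domains(b_by) -> int:
        total = 0
        for chrom, (sa, ea) in a_by.items():
            sb, eb = b_by.get(chrom, (None, None))
            if sb is None:
                continue
            si, ei = iv.intersect(sa, ea, sb, eb)
            keep = (ei - si) >= min_overlap_bp
            si, ei = iv.merge(si[keep], ei[keep])
            total += si.size
        return total

    b_lengths: dict[str, np.ndarray] = {}
    for p in peaks_b:
        if len(p) > layout.length(p.chrom):
            raise ValueError(f"peak longer than chromosome {p.chrom}")
        b_lengths.setdefault(p.chrom, []).append(len(p))
    b_lengths = {c: np.array(v, dtype=np.int64) for c, v in b_lengths.items()}

    observed = count_domains(peaks_b.by_chrom(merged=True))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        shuffled = {}
        for chrom, lens in b_lengths.items():
            L = layout.length(chrom)
            starts = rng.integers(0, L - lens + 1)
            shuffled[chrom] = iv.merge(starts.astype(np.int64),
                                       (starts + lens).astype(np.int64))
        if count_domains(shuffled) >= observed:
            ge += 1
    return observed, (1 + ge) / (n_perm + 1)
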