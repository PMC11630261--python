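"""Peak-to-feature assignment, marked genes, Venn counts, coverage and
metagene profiles.

A peak gets exactly one feature label, taken at its anchor point (summit when
the peak caller reported one, else the midpoint).  A gene counts as *marked*
by a peak set when at least one peak base overlaps its promoter-plus-body
window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _intervals as iv
from .genome_model import (FEATURES, FeatureIndex, GeneModel, GenomeLayout,
                           PeakSet)


@dataclass
class FeatureDistribution:
    """Fractions of peaks per feature label; sums to 1 over non-empty input."""

    fractions: dict[str, float]
    n_peaks: int

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.n_peaks > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")


@dataclass
class MarkedGeneSet:
    mark: str
    condition: str
    genes: frozenset[str]

    def __len__(self):
        return len(self.genes)


@dataclass
class MetaProfile:
    """Mean normalized signal on a TSS->TTS grid: fixed-width upstream bins,
    a scaled gene body, fixed-width downstream bins."""

    values: np.ndarray
    n_flank_up: int
    n_body: int
    n_flank_down: int
    n_genes: int

    @property
    def n_bins(self) -> int:
        return self.n_flank_up + self.n_body + self.n_flank_down


def assign_peaks(peaks: PeakSet, index: FeatureIndex) -> tuple[list[str], FeatureDistribution]:
    """Label each peak by the feature at its anchor point.

    Raises on an empty peak set: a distribution over zero peaks is undefined,
    not zero.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set: feature distribution undefined")
    labels = [index.classify(p.chrom, p.anchor) for p in peaks]
    counts = {f: 0 for f in FEATURES}
    for lab in labels:
        counts[lab] += 1
    n = len(labels)
    dist = FeatureDistribution({f: c / n for f, c in counts.items()}, n)
    return labels, dist


def marked_genes(
    peaks: PeakSet,
    genes: list[GeneModel],
    layout: GenomeLayout,
    promoter_window: int = 2000,
) -> MarkedGeneSet:
    """Genes with >=1 bp of peak overlap on promoter ∪ gene body."""
    merged = peaks.by_chrom(merged=True)
    hit = set()
    for g in genes:
        s, e = merged.get(g.chrom, (None, None))
        if s is None:
            continue
        ws, we = g.gene_window(promoter_window, layout.length(g.chrom))
        if iv.overlaps_point_set(s, e, ws, we):
            hit.add(g.gene_id)
    return MarkedGeneSet(peaks.mark, peaks.condition, frozenset(hit))


def multiway_venn(sets: list[MarkedGeneSet]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for all 2^k - 1 membership patterns.

    Keys are tuples of the mark labels a region belongs to; counts partition
    the union of the input sets.
    """
    if not (2 <= len(sets) <= 4):
        raise ValueError("multiway_venn supports 2 to 4 sets")
    labels = [s.mark for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate mark labels in Venn input")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            inside = set.intersection(*(set(sets[i].genes) for i in combo))
            outside = set().union(*(sets[i].genes for i in range(len(sets)) if i not in combo))
            regions[tuple(labels[i] for i in combo)] = len(inside - outside)
    return regions


def genome_coverage(peaks: PeakSet, layout: GenomeLayout) -> float:
    """Fraction of genome bases covered by the merged peak set."""
    covered = 0
    for chrom, (s, e) in peaks.by_chrom(merged=True).items():
        if chrom not in layout:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        covered += iv.total_bp(s, e)
    return covered / layout.total_bp


def peak_length_histogram(peaks: PeakSet, bin_edges) -> np.ndarray:
    """Peak-length counts per [left, right) bin; every peak lands in one bin."""
    edges = np.asarray(bin_edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = np.array([len(p) for p in peaks], dtype=float)
    counts, _ = np.histogram(lengths, bins=edges)
    # np.histogram closes the last bin on the right; reassign exact-edge hits
    on_last_edge = int(np.sum(lengths == edges[-1]))
    counts[-1] -= on_last_edge
    return counts


def _coverage_arrays(track, layout: GenomeLayout) -> dict[str, np.ndarray]:
    if isinstance(track, PeakSet):
        out = {}
        for chrom, length in layout.as_dict().items():
            arr = np.zeros(length, dtype=np.float64)
            for s, e in zip(*track.by_chrom(merged=True).get(
                    chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))):
                arr[s:e] = 1.0
            out[chrom] = arr
        return out
    return track  # already per-chromosome arrays


def metagene_profile(
    track,
    genes: list[GeneModel],
    layout: GenomeLayout,
    flank_up: int = 1000,
    flank_down: int = 2000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> MetaProfile:
    """Average signal from TSS-flank_up to TTS+flank_down with a scaled body.

    ``track`` is either a :class:`PeakSet` (0/1 occupancy) or a dict of
    per-chromosome per-base float arrays.  Minus-strand genes are reversed so
    the axis always runs TSS -> TTS.  Flank bins running off the chromosome
    are treated as missing and excluded from the mean; body bins of
    zero width (genes shorter than ``body_bins``) likewise.
    """
    if not genes:
        raise ValueError("metagene_profile requires at least one gene")
    if flank_up % flank_bin or flank_down % flank_bin:
        raise ValueError("flank widths must be multiples of flank_bin")
    cov = _coverage_arrays(track, layout)
    n_up = flank_up // flank_bin
    n_down = flank_down // flank_bin
    n_bins = n_up + body_bins + n_down
    acc = np.zeros((len(genes), n_bins), dtype=np.float64)
    acc[:] = np.nan

    for gi, g in enumerate(genes):
        arr = cov[g.chrom]
        L = arr.size
        row = np.full(n_bins, np.nan)
        fwd = g.strand == "+"
        # upstream flank bins, ordered far -> near TSS along the gene axis
        for b in range(n_up):
            if fwd:
                s = g.tss - flank_up + b * flank_bin
                e = s + flank_bin
            else:
                e = g.tss + flank_up - b * flank_bin
                s = e - flank_bin
            if s >= 0 and e <= L:
                row[b] = arr[s:e].mean()
        # scaled body
        bs, be = g.body_start, g.body_end
        glen = be - bs
        for b in range(body_bins):
            lo = bs + (b * glen) // body_bins
            hi = bs + ((b + 1) * glen) // body_bins
            if hi > lo:
                seg = arr[lo:hi]
                idx = n_up + (b if fwd else body_bins - 1 - b)
                row[idx] = seg.mean()
        # downstream flank, ordered near -> far TTS
        for b in range(n_down):
            if fwd:
                s = g.tts + b * flank_bin
                e = s + flank_bin
            else:
                e = g.tts - b * flank_bin
                s = e - flank_bin
            if s >= 0 and e <= L:
                row[n_up + body_bins + b] = arr[s:e].mean()
        acc[gi] = row

    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing bins
        values = np.nanmean(acc, axis=0)
    return MetaProfile(values=values, n_flank_up=n_up, n_body=body_bins,
                       n_flank_down=n_down, n_genes=len(genes))
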