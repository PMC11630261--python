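"""Genome layout, gene models and the six-way genomic-feature partition.

Every base of the genome is assigned exactly one of six feature labels —
promoter, 5' UTR, coding exon, 3' UTR, intron, intergenic — with overlapping
claims resolved by a fixed priority (promoter strongest, intergenic the
default).  All coordinates are 0-based half-open; GFF3 input is converted at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _intervals as iv

MARKS = ("H3K4me3", "H3K9ac", "H3K27me3", "H3K9me2")
CONDITIONS = ("CK", "NaCl", "other")

#: Feature labels in priority order (highest first); also the uint8 codes
#: used internally, so lower code == higher priority.
FEATURES = ("promoter", "utr5", "coding_exon", "utr3", "intron", "intergenic")
FEATURE_CODE = {name: i for i, name in enumerate(FEATURES)}

DEFAULT_PROMOTER_WINDOW = 2000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded, with optional summit."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    summit: int | None = None
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Summit when recorded, else the midpoint — the point used for
        single-label peak-to-feature assignment."""
        return self.summit if self.summit is not None else (self.start + self.end) // 2


@dataclass
class PeakSet:
    """Peak intervals for one histone mark under one condition."""

    mark: str
    condition: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        self.intervals = sorted(self.intervals, key=lambda x: (x.chrom, x.start, x.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self, merged: bool = False) -> dict[str, iv.IntervalArrays]:
        """Per-chromosome (starts, ends) arrays, optionally merged."""
        out: dict[str, list] = {}
        for p in self.intervals:
            out.setdefault(p.chrom, []).append((p.start, p.end))
        arrays = {c: iv.as_arrays(v) for c, v in out.items()}
        if merged:
            arrays = {c: iv.merge(s, e) for c, (s, e) in arrays.items()}
        return arrays

    def validate_against(self, layout: GenomeLayout) -> None:
        for p in self.intervals:
            if p.chrom not in layout:
                raise ValueError(f"peak on unknown chromosome {p.chrom!r}")
            if p.end > layout.length(p.chrom):
                raise ValueError(f"peak {p.chrom}:{p.start}-{p.end} exceeds chromosome")


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-aware body with exon and CDS segments.

    ``tss``/``tts`` are anchor positions: on the + strand tss < tts and the
    body is [tss, tts); on the − strand tss > tts and the body is [tts, tss).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tts")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.body_end - self.body_start

    def promoter(self, window: int, chrom_length: int | None = None) -> tuple[int, int]:
        """Promoter window upstream of the TSS, clipped to the chromosome."""
        if self.strand == "+":
            lo, hi = self.tss - window, self.tss
        else:
            lo, hi = self.tss, self.tss + window
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi

    def gene_window(self, window: int, chrom_length: int | None = None) -> tuple[int, int]:
        """Promoter plus gene body — the span used for peak-to-gene marking."""
        ps, pe = self.promoter(window, chrom_length)
        return min(ps, self.body_start), max(pe, self.body_end)

    def utrs(self) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
        """(utr5, utr3) segments: exonic bases outside the CDS span, split by
        strand side.  Empty when the gene has no annotated CDS."""
        if not self.cds:
            return (), ()
        cds_lo = min(s for s, _ in self.cds)
        cds_hi = max(e for _, e in self.cds)
        before, after = [], []
        for s, e in self.exons:
            if s < cds_lo:
                before.append((s, min(e, cds_lo)))
            if e > cds_hi:
                after.append((max(s, cds_hi), e))
        if self.strand == "+":
            return tuple(before), tuple(after)
        return tuple(after), tuple(before)


class FeatureIndex:
    """Per-chromosome uint8 label arrays: a total six-way genome partition.

    Built by painting gene segments in increasing priority order, so the
    highest-priority claim wins at every base.
    """

    def __init__(self, layout: GenomeLayout, labels: dict[str, np.ndarray], promoter_window: int):
        self.layout = layout
        self.labels = labels
        self.promoter_window = promoter_window

    def classify(self, chrom: str, pos: int) -> str:
        if chrom not in self.layout:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.layout.length(chrom)):
            raise ValueError(f"position {pos} outside {chrom}")
        return FEATURES[int(self.labels[chrom][pos])]

    def feature_bp(self) -> dict[str, int]:
        """Total bases per feature label over the whole genome."""
        counts = np.zeros(len(FEATURES), dtype=np.int64)
        for arr in self.labels.values():
            counts += np.bincount(arr, minlength=len(FEATURES))
        return {name: int(counts[i]) for i, name in enumerate(FEATURES)}

    def segments(self, chrom: str):
        """Yield (start, end, label) runs for one chromosome."""
        arr = self.labels[chrom]
        if arr.size == 0:
            return
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate(([0], change, [arr.size]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            yield int(s), int(e), FEATURES[int(arr[s])]


def build_feature_index(
    genes: list[GeneModel],
    layout: GenomeLayout,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> FeatureIndex:
    """Partition every base into one of the six feature labels.

    Priority: promoter > utr5 > coding_exon > utr3 > intron > intergenic.
    Promoters are clipped at chromosome edges.  An empty gene list gives an
    all-intergenic index.  Genes with no annotated CDS contribute their
    exonic bases as coding_exon.
    """
    if promoter_window <= 0:
        raise ValueError("promoter_window must be positive")
    labels = {
        c: np.full(l, FEATURE_CODE["intergenic"], dtype=np.uint8)
        for c, l in zip(layout.chrom_names, layout.chrom_lengths)
    }
    for g in genes:
        if g.chrom not in layout:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        if g.body_start < 0 or g.body_end > layout.length(g.chrom):
            raise ValueError(f"gene {g.gene_id} outside chromosome bounds")

    def paint(code: int, segs):
        for g, pieces in segs:
            arr = labels[g.chrom]
            for s, e in pieces:
                s = max(int(s), 0)
                e = min(int(e), arr.size)
                if s < e:
                    arr[s:e] = code

    # Increasing priority: intron, utr3, coding_exon, utr5, promoter.
    introns = []
    utr3s = []
    exonics = []
    utr5s = []
    promoters = []
    for g in genes:
        exon_s, exon_e = iv.as_arrays(list(g.exons) or [(g.body_start, g.body_end)])
        exon_s, exon_e = iv.merge(exon_s, exon_e)
        body_s = np.array([g.body_start], dtype=np.int64)
        body_e = np.array([g.body_end], dtype=np.int64)
        in_s, in_e = iv.subtract(body_s, body_e, exon_s, exon_e)
        introns.append((g, list(zip(in_s, in_e))))
        if g.cds:
            u5, u3 = g.utrs()
            utr5s.append((g, list(u5)))
            utr3s.append((g, list(u3)))
            exonics.append((g, list(g.cds)))
        else:
            exonics.append((g, list(zip(exon_s, exon_e))))
        promoters.append((g, [g.promoter(promoter_window, layout.length(g.chrom))]))

    paint(FEATURE_CODE["intron"], introns)
    paint(FEATURE_CODE["utr3"], utr3s)
    paint(FEATURE_CODE["coding_exon"], exonics)
    paint(FEATURE_CODE["utr5"], utr5s)
    paint(FEATURE_CODE["promoter"], promoters)
    return FeatureIndex(layout, labels, promoter_window)


def classify_position(index: FeatureIndex, chrom: str, pos: int) -> str:
    """Feature label at one position (thin wrapper kept for discoverability)."""
    return index.classify(chrom, pos)
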