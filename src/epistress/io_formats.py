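"""Readers and writers for the plain-text formats the pipeline touches.

Every reader validates strictly and raises :class:`FormatError` carrying the
offending line number — no partial silent loads.  Internally all coordinates
are 0-based half-open; GFF3 (1-based inclusive) is converted here at the
boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomeLayout, GenomicInterval, PeakSet

FORMATS = ("bed", "narrowpeak", "gff3", "bedgraph", "tsv")


class FormatError(ValueError):
    """A malformed input line, with file path and 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class FileManifest:
    """One input file: where it lives, what format it is, what role it plays."""

    path: str
    format: str
    role: str

    def __post_init__(self):
        if self.format not in FORMATS:
            raise ValueError(f"unknown format {self.format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# genome layout

def read_genome(path) -> GenomeLayout:
    """Read a two-column chrom-sizes TSV (name, length)."""
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(path, lineno, "expected 2 tab-separated columns")
            try:
                lengths.append(int(parts[1]))
            except ValueError:
                raise FormatError(path, lineno, f"non-integer length {parts[1]!r}") from None
            names.append(parts[0])
    return GenomeLayout(tuple(names), tuple(lengths))


def write_genome(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak

def read_bed(path, layout: GenomeLayout, mark: str = "H3K4me3", condition: str = "other") -> PeakSet:
    """Read BED3/BED6/narrowPeak into a sorted, validated :class:`PeakSet`.

    A 10-column file is treated as narrowPeak: column 10 is the summit offset
    from the interval start (-1 means no summit).  Chromosome names must match
    the layout exactly; any malformed line raises with its line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, lineno, "expected >=3 tab-separated columns")
            chrom = parts[0]
            if chrom not in layout:
                raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(path, lineno, "non-integer coordinates") from None
            if start >= end:
                raise FormatError(path, lineno, f"start {start} >= end {end}")
            if start < 0 or end > layout.length(chrom):
                raise FormatError(path, lineno, "interval outside chromosome bounds")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise FormatError(path, lineno, f"non-numeric score {parts[4]!r}") from None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            summit = None
            if len(parts) >= 10:  # narrowPeak: summit offset in column 10
                try:
                    offset = int(parts[9])
                except ValueError:
                    raise FormatError(path, lineno, "non-integer summit offset") from None
                if offset >= 0:
                    summit = start + offset
                    if not (start <= summit < end):
                        raise FormatError(path, lineno, f"summit {summit} outside interval")
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, summit=summit, name=name, score=score)
            )
    return PeakSet(mark=mark, condition=condition, intervals=intervals)


def write_bed(peaks, path, layout: GenomeLayout | None = None) -> None:
    """Write intervals as BED6 (name/score filled with '.'/0 when absent)."""
    intervals = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    order = {c: i for i, c in enumerate(layout.chrom_names)} if layout else None
    if order is not None:
        intervals = sorted(intervals, key=lambda p: (order.get(p.chrom, 1 << 30), p.start, p.end))
    with open(path, "w") as fh:
        for p in intervals:
            name = p.name if p.name is not None else "."
            score = f"{p.score:g}" if p.score is not None else "0"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, layout: GenomeLayout, bin_size: int | None = None) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-chromosome per-base float arrays."""
    tracks = {c: np.zeros(l, dtype=np.float64) for c, l in layout.as_dict().items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(path, lineno, "expected 4 tab-separated columns")
            chrom = parts[0]
            if chrom not in layout:
                raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise FormatError(path, lineno, "malformed coordinates or value") from None
            if start >= end or start < 0 or end > layout.length(chrom):
                raise FormatError(path, lineno, "interval invalid or outside chromosome")
            tracks[chrom][start:end] = value
    return tracks


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path, layout: GenomeLayout) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates become 0-based half-open.  One model
    per gene; when a gene carries several mRNAs the first one (file order)
    defines the structure.  A child extending outside its parent span, or a
    feature with no strand, is rejected with its line number.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise FormatError(path, lineno, f"expected {_GFF_COLS} columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = parts
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            if chrom not in layout:
                raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(path, lineno, "non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise FormatError(path, lineno, f"invalid span {start1}..{end1}")
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if end > layout.length(chrom):
                raise FormatError(path, lineno, "feature outside chromosome bounds")
            if strand not in ("+", "-"):
                raise FormatError(path, lineno, f"missing or invalid strand {strand!r}")
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(path, lineno, "gene feature without ID attribute")
                if gid in genes:
                    raise FormatError(path, lineno, f"duplicate gene ID {gid!r}")
                genes[gid] = {
                    "chrom": chrom, "start": start, "end": end, "strand": strand,
                    "mrna": None, "exons": [], "cds": [], "lineno": lineno,
                }
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise FormatError(path, lineno, "mRNA without ID/Parent")
                if parent not in genes:
                    raise FormatError(path, lineno, f"mRNA parent {parent!r} not seen")
                g = genes[parent]
                if not (g["start"] <= start and end <= g["end"]):
                    raise FormatError(path, lineno, "mRNA outside parent gene span")
                if g["mrna"] is None:  # first mRNA wins
                    g["mrna"] = mid
                    mrna_to_gene[mid] = parent
            else:  # exon / CDS
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(path, lineno, f"{ftype} without Parent")
                gid = mrna_to_gene.get(parent, parent if parent in genes else None)
                if gid is None:
                    continue  # child of a non-first mRNA
                g = genes[gid]
                if not (g["start"] <= start and end <= g["end"]):
                    raise FormatError(path, lineno, f"{ftype} outside parent span")
                g["exons" if ftype == "exon" else "cds"].append((start, end))

    models = []
    for gid, g in genes.items():
        if g["strand"] == "+":
            tss, tts = g["start"], g["end"]
        else:
            tss, tts = g["end"], g["start"]
        exons = tuple(sorted(g["exons"])) or ((g["start"], g["end"]),)
        models.append(
            GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"], tss=tss,
                      tts=tts, exons=exons, cds=tuple(sorted(g["cds"])))
        )
    models.sort(key=lambda m: (m.chrom, m.body_start, m.gene_id))
    return models


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models back out as GFF3 (gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.body_start + 1, g.body_end
            fh.write(f"{g.chrom}\t.\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mid}\n")
            for s, e in g.cds:
                fh.write(f"{g.chrom}\t.\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={mid}\n")


# ---------------------------------------------------------------------------
# tabular inputs

def read_expression_table(path):
    """Read an FPKM TSV (gene + one column per sample) into a DataFrame.

    Sample columns must be named ``<condition>_<replicate>``.  Rejects
    negative FPKM and duplicated gene ids.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene'")
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: {int(dup.sum())} duplicate gene ids")
    df = df.set_index("gene")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing FPKM values")
    return df


def read_de_table(path):
    """Read a DE TSV (gene, log2fc, pvalue, fdr) with range validation."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "pvalue", "fdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: {int(dup.sum())} duplicate gene ids")
    for col in ("pvalue", "fdr"):
        bad = ~df[col].between(0, 1)
        if bad.any():
            raise ValueError(f"{path}: {col} outside [0,1] for {int(bad.sum())} rows")
    if not np.isfinite(df["log2fc"]).all():
        raise ValueError(f"{path}: non-finite log2fc")
    return df.set_index("gene")


def read_metabolite_table(path):
    """Read a metabolite TSV (id, ion_mode, vip, fc, pvalue) with validation."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "ion_mode", "vip", "fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if not df["ion_mode"].isin(["pos", "neg"]).all():
        raise ValueError(f"{path}: ion_mode must be 'pos' or 'neg'")
    if (df["vip"] < 0).any():
        raise ValueError(f"{path}: negative VIP")
    if (df["fc"] <= 0).any():
        raise ValueError(f"{path}: fold change must be positive")
    if not df["pvalue"].between(0, 1).all():
        raise ValueError(f"{path}: p-value outside [0,1]")
    dup = df["id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: {int(dup.sum())} duplicate metabolite ids")
    return df.set_index("id")


def read_table(path, schema: str):
    """Dispatch on schema name: expression | de | metabolite."""
    readers = {
        "expression": read_expression_table,
        "de": read_de_table,
        "metabolite": read_metabolite_table,
    }
    if schema not in readers:
        raise ValueError(f"unknown schema {schema!r}")
    return readers[schema](path)


def condition_of_sample(sample: str) -> str:
    """Condition label encoded in a sample column name ``<condition>_<rep>``."""
    if "_" not in sample:
        raise ValueError(f"sample name {sample!r} lacks a _<replicate> suffix")
    return sample.rsplit("_", 1)[0]
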