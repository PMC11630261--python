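"""Shared fixtures: toy genomes and session-scoped simulated worlds."""

from __future__ import annotations

import numpy as np
import pytest

from epistress import synthetic_data as sd
from epistress.genome_model import GeneModel, GenomeLayout, GenomicInterval, PeakSet


@pytest.fixture
def tiny_layout():
    return GenomeLayout(("chr1", "chr2"), (10_000, 8_000))


@pytest.fixture
def toy_genes(tiny_layout):
    """Two genes: a plus-strand gene with UTRs and a minus-strand single-exon
    gene, both on chr1."""
    g1 = GeneModel(
        gene_id="gA", chrom="chr1", strand="+", tss=3000, tts=4000,
        exons=((3000, 3400), (3600, 4000)),
        cds=((3100, 3400), (3600, 3900)),
    )
    g2 = GeneModel(
        gene_id="gB", chrom="chr1", strand="-", tss=7000, tts=6200,
        exons=((6200, 7000),), cds=(),
    )
    return [g1, g2]


def make_peaks(intervals, mark="H3K4me3", condition="CK"):
    return PeakSet(mark=mark, condition=condition,
                   intervals=[GenomicInterval(*t) for t in intervals])


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions: 10-Mb genome, 2000 genes, 5 replicates."""
    return sd.simulate(sd.SimConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_world():
    return sd.simulate(sd.SimConfig.noise_free(seed=23))


def per_base_bool(layout, intervals_by_chrom):
    """Independent per-base boolean occupancy arrays (oracle helper)."""
    out = {c: np.zeros(l, dtype=bool) for c, l in layout.as_dict().items()}
    for chrom, pairs in intervals_by_chrom.items():
        for s, e in pairs:
            out[chrom][s:e] = True
    return out
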