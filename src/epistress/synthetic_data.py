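"""A miniature genome with planted ground truth for every pipeline stage.

The generator builds one coherent world: a hidden chromatin-state path
sampled from a known Bernoulli-emission HMM produces the four marks' peak
sets; genes are laid out with guaranteed inter-gene spacing (so per-gene
edits never bleed into a neighbour); a seeded subset of promoters is forced
bivalent (H3K9ac + H3K27me3); expression is lognormal with multiplicative
mark coupling; the stress condition applies planted mark gain/loss coupled
to expression shifts; reChIP sets are the realized bivalent domains minus
seeded dropouts; the metabolite table is generated independently with known
differential classes.

Everything is driven by one :class:`SimConfig`; an identical seed yields a
byte-identical output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _intervals as iv
from . import io_formats
from .bivalency import call_bivalent
from .genome_model import GeneModel, GenomeLayout, GenomicInterval, PeakSet

GENE_MARKS = ("H3K4me3", "H3K9ac", "H3K27me3")
ALL_MARKS = ("H3K4me3", "H3K9ac", "H3K27me3", "H3K9me2")

#: (mark, change) planted on upregulated genes; the mirror set goes on
#: downregulated genes.
UP_PROGRAM = (("H3K4me3", "gain"), ("H3K9ac", "gain"), ("H3K27me3", "loss"))
DOWN_PROGRAM = (("H3K4me3", "loss"), ("H3K9ac", "loss"), ("H3K27me3", "gain"))


def default_hmm_truth():
    """Six-state truth model over (H3K4me3, H3K9ac, H3K27me3, H3K9me2).

    States: active promoter, transcription, bivalent, polycomb,
    heterochromatin, low.  Transition persistence is tuned so runs of marked
    bins give peaks mostly in the 200-700 bp band at 200-bp bins.
    """
    E = np.array([
        [0.90, 0.85, 0.05, 0.02],
        [0.65, 0.50, 0.08, 0.02],
        [0.08, 0.75, 0.80, 0.02],
        [0.04, 0.05, 0.85, 0.05],
        [0.02, 0.02, 0.08, 0.90],
        [0.01, 0.01, 0.02, 0.04],
    ])
    weights = np.array([0.06, 0.08, 0.06, 0.10, 0.35, 0.35])
    diag = np.array([0.65, 0.70, 0.70, 0.75, 0.90, 0.88])
    K = E.shape[0]
    A = np.zeros((K, K))
    for i in range(K):
        off = weights.copy()
        off[i] = 0.0
        off /= off.sum()
        A[i] = off * (1 - diag[i])
        A[i, i] = diag[i]
    pi = weights / weights.sum()
    return pi, A, E


def noise_free_hmm_truth():
    """Deterministic-emission truth: each state emits an exact mark pattern
    and no state carries both H3K9ac and H3K27me3, so bivalent co-occurrence
    exists only where the generator plants it."""
    E = np.array([
        [1.0, 1.0, 0.0, 0.0],   # active promoter (K4 + K9ac)
        [1.0, 0.0, 0.0, 0.0],   # K4 only
        [0.0, 1.0, 0.0, 0.0],   # K9ac only
        [0.0, 0.0, 1.0, 0.0],   # polycomb
        [0.0, 0.0, 0.0, 1.0],   # heterochromatin
        [0.0, 0.0, 0.0, 0.0],   # low
    ])
    weights = np.array([0.07, 0.07, 0.07, 0.11, 0.34, 0.34])
    diag = np.array([0.65, 0.70, 0.70, 0.75, 0.90, 0.88])
    K = E.shape[0]
    A = np.zeros((K, K))
    for i in range(K):
        off = weights.copy()
        off[i] = 0.0
        off /= off.sum()
        A[i] = off * (1 - diag[i])
        A[i, i] = diag[i]
    return weights / weights.sum(), A, E


@dataclass
class SimConfig:
    """All knobs of the synthetic world.  Defaults are the study conditions
    the rest of the package is exercised under: a 10-Mb seven-chromosome
    genome, 2000 genes, four marks, two conditions, five replicates."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (1_800_000, 1_600_000, 1_500_000,
                                      1_400_000, 1_300_000, 1_200_000, 1_200_000)
    n_genes: int = 2000
    gene_len_median: float = 2000.0
    gene_len_sigma: float = 0.35       # lognormal sigma on ln-length
    gene_len_range: tuple[int, int] = (600, 5000)
    gene_margin: int = 200             # clearance beyond promoters between gene windows
    promoter_window: int = 2000
    bin_size: int = 200
    hmm_truth: tuple = field(default_factory=default_hmm_truth)
    # bivalency
    frac_bivalent: float = 0.35
    bivalent_core_len: int = 600
    bivalent_margin: int = 100
    # expression coupling
    expr_log2_mean: float = 2.2
    expr_log2_sigma: float = 1.6
    frac_silent: float = 0.08
    active_mult: float = 4.0           # FPKM multiplier per active promoter mark
    repressive_div: float = 2.0        # FPKM divisor when H3K27me3 is present
    rep_sigma: float = 0.25            # lognormal (log2) replicate noise
    bivalent_sigma_mult: float = 3.0   # bivalent genes are more variable
    n_reps: int = 5
    # condition shift
    n_up: int = 150
    n_down: int = 150
    de_min_fpkm: float = 5.0
    lfc_base: float = 2.0
    lfc_exp_scale: float = 0.7         # |lfc| = lfc_base + Exp(scale)
    concordant_prob: float = 0.7       # per applicable mark on a DE gene
    churn_rate: float = 0.02           # uncoupled per-gene per-mark toggles
    gain_peak_len: tuple[int, int] = (400, 900)
    label_noise: float = 0.0           # unrecorded corruption of mark edits
    # reChIP
    rechip_dropout_ab: float = 0.07
    rechip_dropout_ba: float = 0.07
    # transposable elements
    te_coverage: dict = field(default_factory=lambda: {
        "Gypsy": 0.18, "Copia": 0.09, "LINE": 0.05, "SINE": 0.02, "DNA": 0.08})
    te_het_bias: float = 0.7           # fraction of TEs seeded in heterochromatin
    # metabolites
    n_metabolites: dict = field(default_factory=lambda: {"pos": 622, "neg": 537})
    n_diff_metabolites: dict = field(default_factory=lambda: {
        "pos": (139, 51), "neg": (158, 39)})  # (up, down) per ion mode

    def validate(self) -> None:
        probs = {
            "frac_bivalent": self.frac_bivalent, "frac_silent": self.frac_silent,
            "concordant_prob": self.concordant_prob, "churn_rate": self.churn_rate,
            "label_noise": self.label_noise,
            "rechip_dropout_ab": self.rechip_dropout_ab,
            "rechip_dropout_ba": self.rechip_dropout_ba,
            "te_het_bias": self.te_het_bias,
        }
        for name, p in probs.items():
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must lie in [0,1], got {p}")
        if self.gene_margin <= 0:
            raise ValueError("gene_margin must be positive")
        if self.n_up + self.n_down + int(self.churn_rate * 3 * self.n_genes) > self.n_genes:
            raise ValueError("planted change rates exceed the gene count")
        pi, A, E = self.hmm_truth
        if np.any(E < 0) or np.any(E > 1):
            raise ValueError("emission probabilities outside [0,1]")
        if abs(np.sum(pi) - 1) > 1e-9 or np.abs(np.sum(A, axis=1) - 1).max() > 1e-9:
            raise ValueError("HMM truth rows must be stochastic")
        for mode, (up, down) in self.n_diff_metabolites.items():
            if up + down > self.n_metabolites[mode]:
                raise ValueError(f"too many differential metabolites for {mode}")

    @classmethod
    def noise_free(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A deterministic-emission, zero-noise world: planted structure is
        the only structure."""
        cfg = cls(seed=seed, hmm_truth=noise_free_hmm_truth(), rep_sigma=0.0,
                  churn_rate=0.0, label_noise=0.0, rechip_dropout_ab=0.0,
                  rechip_dropout_ba=0.0, concordant_prob=1.0,
                  bivalent_sigma_mult=1.0)
        return replace(cfg, **overrides)


@dataclass
class SimTruth:
    """Machine-readable record of everything the generator planted."""

    state_paths: dict[str, np.ndarray]
    bivalent_genes: tuple[str, ...]
    bivalent_domains: tuple[GenomicInterval, ...]
    mark_status: pd.DataFrame          # gene x mark planted statuses
    de: pd.DataFrame                   # planted DE genes: direction, lfc
    gene_means: pd.DataFrame           # per-gene true mean FPKM per condition
    metabolites: pd.DataFrame          # id, ion_mode, class

    @property
    def de_up(self) -> frozenset[str]:
        return frozenset(self.de.index[self.de["direction"] == "up"])

    @property
    def de_down(self) -> frozenset[str]:
        return frozenset(self.de.index[self.de["direction"] == "down"])

    def concordant_classes(self) -> dict[str, frozenset[str]]:
        """Planted membership of the six mark-change/expression classes."""
        out = {}
        for direction, program in (("up", UP_PROGRAM), ("down", DOWN_PROGRAM)):
            degs = self.de_up if direction == "up" else self.de_down
            for mark, change in program:
                members = frozenset(
                    g for g in degs
                    if self.mark_status.loc[g, mark] == change)
                out[f"{mark}-{change}/{direction}"] = members
        return out


@dataclass
class SimWorld:
    """The generated world held in memory, plus its truth."""

    config: SimConfig
    layout: GenomeLayout
    genes: list[GeneModel]
    peaks: dict[tuple[str, str], PeakSet]     # (mark, condition) -> PeakSet
    te_classes: dict[str, dict[str, iv.IntervalArrays]]
    expression: pd.DataFrame
    metabolites: pd.DataFrame
    rechip_ab: PeakSet
    rechip_ba: PeakSet
    truth: SimTruth


# ---------------------------------------------------------------------------
# helpers on per-chromosome merged interval dicts

def _sets_to_peakset(sets: dict[str, iv.IntervalArrays], mark: str,
                     condition: str, layout: GenomeLayout) -> PeakSet:
    intervals = []
    for chrom in layout.chrom_names:
        se = sets.get(chrom)
        if se is None:
            continue
        for i, (s, e) in enumerate(zip(*se)):
            intervals.append(GenomicInterval(chrom, int(s), int(e),
                                             name=f"{mark}_{condition}_{chrom}_{i}"))
    return PeakSet(mark=mark, condition=condition, intervals=intervals)


def _clear_span(sets: dict, chrom: str, lo: int, hi: int) -> None:
    se = sets.get(chrom)
    if se is None:
        return
    sets[chrom] = iv.subtract(se[0], se[1],
                              np.array([lo], np.int64), np.array([hi], np.int64))


def _add_span(sets: dict, chrom: str, lo: int, hi: int) -> None:
    se = sets.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
    sets[chrom] = iv.merge(np.append(se[0], lo), np.append(se[1], hi))


def _window_bp(sets: dict, chrom: str, lo: int, hi: int) -> int:
    se = sets.get(chrom)
    if se is None:
        return 0
    return iv.overlap_bp_with(se[0], se[1], lo, hi)


# ---------------------------------------------------------------------------
# generation stages

def _place_genes(cfg: SimConfig, layout: GenomeLayout, rng) -> list[GeneModel]:
    total = layout.total_bp
    alloc = [int(round(cfg.n_genes * l / total)) for l in layout.chrom_lengths]
    while sum(alloc) > cfg.n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < cfg.n_genes:
        alloc[int(np.argmin(alloc))] += 1
    genes = []
    gid = 0
    w, m = cfg.promoter_window, cfg.gene_margin
    for chrom, L, n in zip(layout.chrom_names, layout.chrom_lengths, alloc):
        lengths = np.exp(rng.normal(np.log(cfg.gene_len_median), cfg.gene_len_sigma, n))
        lengths = np.clip(lengths.astype(np.int64), *cfg.gene_len_range)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        # strand-aware minimum gaps keep promoter+body windows pairwise
        # disjoint: a junction needs room for every promoter facing into it
        min_gaps = np.empty(n + 1, dtype=np.int64)
        min_gaps[0] = m + (w if n and strands[0] == "+" else 0)
        for i in range(1, n):
            min_gaps[i] = (m + (w if strands[i - 1] == "-" else 0)
                           + (w if strands[i] == "+" else 0))
        min_gaps[n] = m + (w if n and strands[-1] == "-" else 0)
        need = int(lengths.sum()) + int(min_gaps.sum())
        if need > L:  # shrink gene bodies; the spacing is non-negotiable
            avail = L - int(min_gaps.sum())
            lengths = np.maximum((lengths * avail / lengths.sum()).astype(np.int64),
                                 cfg.gene_len_range[0])
        slack = L - int(lengths.sum()) - int(min_gaps.sum())
        extra = (rng.dirichlet(np.ones(n + 1)) * slack).astype(np.int64)
        pos = int(min_gaps[0]) + int(extra[0])
        for i in range(n):
            start = pos
            end = start + int(lengths[i])
            strand = str(strands[i])
            exons, cds = _gene_structure(start, end, strand, rng)
            gid += 1
            tss, tts = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(gene_id=f"g{gid:04d}", chrom=chrom, strand=strand,
                                   tss=tss, tts=tts, exons=exons, cds=cds))
            pos = end + int(min_gaps[i + 1]) + int(extra[i + 1])
    return genes


def _gene_structure(start: int, end: int, strand: str, rng):
    """Random exon/intron layout with UTR-trimmed CDS."""
    length = end - start
    n_ex = int(rng.integers(1, 5))
    if n_ex == 1 or length < 1200:
        exons = ((start, end),)
    else:
        cuts = np.sort(rng.choice(np.arange(start + 150, end - 150, 50),
                                  size=2 * (n_ex - 1), replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = tuple((bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex))
    exonic = sum(e - s for s, e in exons)
    utr5 = int(rng.integers(30, 150))
    utr3 = int(rng.integers(50, 250))
    if exonic < utr5 + utr3 + 300:
        return exons, exons  # too short for UTRs: fully coding
    left_trim, right_trim = (utr5, utr3) if strand == "+" else (utr3, utr5)
    cds = []
    remaining_left = left_trim
    pieces = []
    for s, e in exons:
        if remaining_left >= e - s:
            remaining_left -= e - s
            continue
        pieces.append((s + remaining_left, e))
        remaining_left = 0
    remaining_right = right_trim
    for s, e in reversed(pieces):
        if remaining_right >= e - s:
            remaining_right -= e - s
            continue
        cds.append((s, e - remaining_right))
        remaining_right = 0
    cds = tuple(sorted(cds))
    return exons, cds


def _sample_states_and_peaks(cfg: SimConfig, layout: GenomeLayout, rng):
    pi, A, E = cfg.hmm_truth
    K = len(pi)
    state_paths: dict[str, np.ndarray] = {}
    mark_sets = {m: {} for m in ALL_MARKS}
    bs = cfg.bin_size
    for chrom, L in layout.as_dict().items():
        n = -(-L // bs)
        path = np.empty(n, dtype=np.int64)
        path[0] = rng.choice(K, p=pi)
        u = rng.random(n)
        for t in range(1, n):
            path[t] = np.searchsorted(np.cumsum(A[path[t - 1]]), u[t])
        state_paths[chrom] = path + 1
        for mi, mark in enumerate(ALL_MARKS):
            on = rng.random(n) < E[path, mi]
            idx = np.flatnonzero(on)
            if idx.size == 0:
                mark_sets[mark][chrom] = (np.empty(0, np.int64), np.empty(0, np.int64))
                continue
            starts = idx * bs
            ends = np.minimum(starts + bs, L)
            mark_sets[mark][chrom] = iv.merge(starts.astype(np.int64),
                                              ends.astype(np.int64))
    return state_paths, mark_sets


def _plant_bivalent(cfg: SimConfig, layout, genes, ck_sets, rng):
    n_biv = int(round(cfg.frac_bivalent * len(genes)))
    order = rng.permutation(len(genes))
    chosen = sorted(order[:n_biv].tolist())
    biv_genes, domains = [], []
    for gi in chosen:
        g = genes[gi]
        ps, pe = g.promoter(cfg.promoter_window, layout.length(g.chrom))
        if pe - ps < cfg.bivalent_core_len + 2 * cfg.bivalent_margin:
            continue
        if g.strand == "+":  # core hugs the TSS side of the window
            core_e = pe - cfg.bivalent_margin
            core_s = core_e - cfg.bivalent_core_len
        else:
            core_s = ps + cfg.bivalent_margin
            core_e = core_s + cfg.bivalent_core_len
        for mark in ("H3K9ac", "H3K27me3"):
            _clear_span(ck_sets[mark], g.chrom, ps, pe)
            _add_span(ck_sets[mark], g.chrom, core_s, core_e)
        biv_genes.append(g.gene_id)
        domains.append(GenomicInterval(g.chrom, core_s, core_e, name=g.gene_id))
    return tuple(biv_genes), tuple(domains)


def _expression_means(cfg: SimConfig, layout, genes, ck_sets, biv_genes, rng):
    biv = set(biv_genes)
    means = {}
    for g in genes:
        base = float(2 ** rng.normal(cfg.expr_log2_mean, cfg.expr_log2_sigma))
        silent = rng.random() < cfg.frac_silent
        if silent:
            means[g.gene_id] = 0.0
            continue
        if g.gene_id in biv:
            means[g.gene_id] = base  # intermediate regime: no coupling
            continue
        ws, we = g.gene_window(cfg.promoter_window, layout.length(g.chrom))
        for mark, effect in (("H3K4me3", cfg.active_mult), ("H3K9ac", cfg.active_mult)):
            if _window_bp(ck_sets[mark], g.chrom, ws, we) > 0:
                base *= effect
        if _window_bp(ck_sets["H3K27me3"], g.chrom, ws, we) > 0:
            base /= cfg.repressive_div
        means[g.gene_id] = base
    return pd.Series(means, name="mean_ck")


#: bp multiplier for gain-by-replacement; 1/4.2 < 0.25 keeps the call below
#: the Jaccard stability floor whatever the old/new overlap.
_GAIN_REPLACE_FACTOR = 4.2


def _apply_toggle(cfg, layout, sets, g, change, rng) -> bool:
    """Plant one mark change over one gene's window; True when applied.

    gain on an unmarked gene adds a promoter peak; gain on a marked gene
    replaces its window occupancy with >= 4.2x the basepairs (an unambiguous
    gain under the Jaccard-floor rule); loss clears the window.  Edits never
    leave the gene's own window, so neighbours are untouched.
    """
    ws, we = g.gene_window(cfg.promoter_window, layout.length(g.chrom))
    old_bp = _window_bp(sets, g.chrom, ws, we)
    if change == "gain":
        if old_bp == 0:
            ps, pe = g.promoter(cfg.promoter_window, layout.length(g.chrom))
            lo_len, hi_len = cfg.gain_peak_len
            plen = int(rng.integers(lo_len, hi_len + 1))
            plen = min(plen, pe - ps - 100)
            if plen < 200:
                return False
            off = int(rng.integers(50, pe - ps - plen - 49))
            _add_span(sets, g.chrom, ps + off, ps + off + plen)
            return True
        need = int(np.ceil(_GAIN_REPLACE_FACTOR * old_bp))
        if need > (we - ws) - 100:
            return False
        _clear_span(sets, g.chrom, ws, we)
        start = ws + int(rng.integers(0, (we - ws) - need - 99)) + 50
        _add_span(sets, g.chrom, start, start + need)
        return True
    if old_bp == 0:
        return False
    _clear_span(sets, g.chrom, ws, we)
    return True


def _plant_dynamics(cfg: SimConfig, layout, genes, ck_sets, nacl_sets,
                    mean_ck: pd.Series, rng):
    eligible = [g for g in genes if mean_ck[g.gene_id] >= cfg.de_min_fpkm]
    if len(eligible) < cfg.n_up + cfg.n_down:
        raise ValueError("not enough expressed genes to plant the requested DEGs")
    order = rng.permutation(len(eligible))
    up = [eligible[i] for i in order[:cfg.n_up]]
    down = [eligible[i] for i in order[cfg.n_up:cfg.n_up + cfg.n_down]]
    de_rows = []
    status = pd.DataFrame("", index=[g.gene_id for g in genes], columns=GENE_MARKS)
    mean_nacl = mean_ck.copy().rename("mean_nacl")
    touched = set()
    for direction, program, members in (("up", UP_PROGRAM, up),
                                        ("down", DOWN_PROGRAM, down)):
        for g in members:
            lfc = cfg.lfc_base + float(rng.exponential(cfg.lfc_exp_scale))
            factor = 2 ** lfc if direction == "up" else 2 ** (-lfc)
            mean_nacl[g.gene_id] = mean_ck[g.gene_id] * factor
            de_rows.append({"gene": g.gene_id, "direction": direction, "lfc": lfc})
            touched.add(g.gene_id)
            for mark, change in program:
                if rng.random() >= cfg.concordant_prob:
                    continue
                if _apply_toggle(cfg, layout, nacl_sets[mark], g, change, rng):
                    status.loc[g.gene_id, mark] = change
    # uncoupled churn on untouched genes
    for g in genes:
        if g.gene_id in touched:
            continue
        for mark in GENE_MARKS:
            if rng.random() < cfg.churn_rate:
                ws, we = g.gene_window(cfg.promoter_window, layout.length(g.chrom))
                change = "loss" if _window_bp(nacl_sets[mark], g.chrom, ws, we) > 0 else "gain"
                if _apply_toggle(cfg, layout, nacl_sets[mark], g, change, rng):
                    status.loc[g.gene_id, mark] = change
    # fill remaining statuses from CK presence
    for g in genes:
        ws, we = g.gene_window(cfg.promoter_window, layout.length(g.chrom))
        for mark in GENE_MARKS:
            if status.loc[g.gene_id, mark] == "":
                marked = _window_bp(ck_sets[mark], g.chrom, ws, we) > 0
                status.loc[g.gene_id, mark] = "stable" if marked else "absent"
    # unrecorded corruption
    if cfg.label_noise > 0:
        for g in genes:
            for mark in GENE_MARKS:
                if rng.random() < cfg.label_noise:
                    ws, we = g.gene_window(cfg.promoter_window, layout.length(g.chrom))
                    change = ("loss" if _window_bp(nacl_sets[mark], g.chrom, ws, we) > 0
                              else "gain")
                    _apply_toggle(cfg, layout, nacl_sets[mark], g, change, rng)
    de = pd.DataFrame(de_rows).set_index("gene") if de_rows else pd.DataFrame(
        columns=["direction", "lfc"])
    return de, status, mean_nacl


def _replicates(cfg: SimConfig, mean_ck, mean_nacl, biv_genes, rng) -> pd.DataFrame:
    biv = set(biv_genes)
    data = {}
    for cond, means in (("CK", mean_ck), ("NaCl", mean_nacl)):
        for r in range(1, cfg.n_reps + 1):
            col = []
            for gid, mu in means.items():
                sigma = cfg.rep_sigma * (cfg.bivalent_sigma_mult if gid in biv else 1.0)
                noise = 2 ** rng.normal(0.0, sigma) if sigma > 0 else 1.0
                col.append(mu * noise)
            data[f"{cond}_{r}"] = col
    return pd.DataFrame(data, index=list(mean_ck.index)).rename_axis("gene")


def _place_tes(cfg: SimConfig, layout, state_paths, rng):
    pi, A, E = cfg.hmm_truth
    het_state = int(np.argmax(E[:, ALL_MARKS.index("H3K9me2")])) + 1
    bs = cfg.bin_size
    het_bins = []
    for chrom, path in state_paths.items():
        idx = np.flatnonzero(path == het_state)
        het_bins.extend((chrom, int(i)) for i in idx)
    te_classes = {}
    chroms = list(layout.chrom_names)
    lens = np.array(layout.chrom_lengths, dtype=float)
    for cls, frac in cfg.te_coverage.items():
        target = frac * layout.total_bp
        placed = {c: [] for c in chroms}
        acc = 0
        while acc < target:
            length = int(np.clip(rng.lognormal(np.log(2500), 0.6), 300, 20000))
            if het_bins and rng.random() < cfg.te_het_bias:
                chrom, b = het_bins[int(rng.integers(len(het_bins)))]
                start = b * bs + int(rng.integers(0, bs))
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
                start = int(rng.integers(0, layout.length(chrom)))
            end = min(start + length, layout.length(chrom))
            if end - start >= 300:
                placed[chrom].append((start, end))
                acc += end - start
        te_classes[cls] = {c: iv.merge(*iv.as_arrays(v))
                           for c, v in placed.items() if v}
    return te_classes


def _metabolites(cfg: SimConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for mode in ("pos", "neg"):
        n = cfg.n_metabolites[mode]
        n_up, n_down = cfg.n_diff_metabolites[mode]
        for i in range(n):
            mid = f"M_{mode}_{i + 1:04d}"
            if i < n_up:
                klass = "up"
                vip = float(rng.uniform(1.05, 3.0))
                fc = float(rng.uniform(1.6, 5.0))
                p = float(rng.uniform(1e-5, 0.045))
            elif i < n_up + n_down:
                klass = "down"
                vip = float(rng.uniform(1.05, 3.0))
                fc = float(rng.uniform(0.15, 0.6))
                p = float(rng.uniform(1e-5, 0.045))
            else:
                klass = "none"
                fail = int(rng.integers(0, 3))  # which gate this null row fails
                vip = float(rng.uniform(0.0, 0.95)) if fail == 0 else float(rng.uniform(0.5, 2.5))
                fc = float(rng.uniform(0.75, 1.4)) if fail == 1 else float(rng.uniform(0.2, 4.0))
                p = float(rng.uniform(0.055, 1.0)) if fail == 2 else float(rng.uniform(0.0, 1.0))
                if vip > 1.0 and (fc > 1.5 or fc < 0.667) and p < 0.05:
                    p = float(rng.uniform(0.055, 1.0))  # keep the row truly null
            rows.append({"id": mid, "ion_mode": mode, "vip": vip, "fc": fc,
                         "pvalue": p, "class": klass})
    df = pd.DataFrame(rows).set_index("id")
    truth = df[["ion_mode", "class"]].copy()
    return df.drop(columns=["class"]), truth


# ---------------------------------------------------------------------------
# entry points

def simulate(config: SimConfig, outdir=None) -> SimWorld:
    """Generate the full world; optionally write it to ``outdir``.

    Identical config (including seed) gives byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = GenomeLayout(tuple(f"chr{i + 1}" for i in range(len(config.chrom_lengths))),
                          tuple(config.chrom_lengths))
    genes = _place_genes(config, layout, rng)
    state_paths, ck_sets = _sample_states_and_peaks(config, layout, rng)
    biv_genes, biv_domains = _plant_bivalent(config, layout, genes, ck_sets, rng)
    mean_ck = _expression_means(config, layout, genes, ck_sets, biv_genes, rng)
    nacl_sets = {m: {c: (s.copy(), e.copy()) for c, (s, e) in by.items()}
                 for m, by in ck_sets.items()}
    de, status, mean_nacl = _plant_dynamics(config, layout, genes, ck_sets,
                                            nacl_sets, mean_ck, rng)
    expression = _replicates(config, mean_ck, mean_nacl, biv_genes, rng)
    te_classes = _place_tes(config, layout, state_paths, rng)
    metabolite_table, metabolite_truth = _metabolites(config, rng)

    peaks = {}
    for mark in ALL_MARKS:
        peaks[(mark, "CK")] = _sets_to_peakset(ck_sets[mark], mark, "CK", layout)
        peaks[(mark, "NaCl")] = _sets_to_peakset(nacl_sets[mark], mark, "NaCl", layout)

    # reChIP from the *realized* CK bivalent domains
    realized = call_bivalent(peaks[("H3K9ac", "CK")], peaks[("H3K27me3", "CK")])
    ab_keep = [d for d in realized.domains if rng.random() >= config.rechip_dropout_ab]
    ba_keep = [d for d in realized.domains if rng.random() >= config.rechip_dropout_ba]
    rechip_ab = PeakSet(mark="H3K27me3", condition="CK", intervals=ab_keep)
    rechip_ba = PeakSet(mark="H3K9ac", condition="CK", intervals=ba_keep)

    truth = SimTruth(
        state_paths=state_paths,
        bivalent_genes=biv_genes,
        bivalent_domains=biv_domains,
        mark_status=status,
        de=de,
        gene_means=pd.concat([mean_ck, mean_nacl], axis=1),
        metabolites=metabolite_truth,
    )
    world = SimWorld(config=config, layout=layout, genes=genes, peaks=peaks,
                     te_classes=te_classes, expression=expression,
                     metabolites=metabolite_table, rechip_ab=rechip_ab,
                     rechip_ba=rechip_ba, truth=truth)
    if outdir is not None:
        write_world(world, outdir)
    return world


def write_world(world: SimWorld, outdir) -> dict[str, str]:
    """Write every input file of the pipeline, plus the truth report."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    io_formats.write_genome(world.layout, p("genome.tsv"))
    io_formats.write_gff3(world.genes, p("genes.gff3"))
    for (mark, cond), ps in sorted(world.peaks.items()):
        io_formats.write_bed(ps, p(f"peaks_{mark}_{cond}.bed"), world.layout)
    te_intervals = []
    for cls, by in sorted(world.te_classes.items()):
        for chrom in world.layout.chrom_names:
            se = by.get(chrom)
            if se is None:
                continue
            te_intervals.extend(GenomicInterval(chrom, int(s), int(e), name=cls)
                                for s, e in zip(*se))
    io_formats.write_bed(te_intervals, p("te.bed"), world.layout)
    world.expression.round(4).to_csv(p("expression.tsv"), sep="\t")
    world.metabolites.round(6).to_csv(p("metabolites.tsv"), sep="\t")
    io_formats.write_bed(world.rechip_ab, p("rechip_ab.bed"), world.layout)
    io_formats.write_bed(world.rechip_ba, p("rechip_ba.bed"), world.layout)
    truth_report(world.truth, os.path.join(outdir, "truth"))
    return paths


def truth_report(truth: SimTruth, outdir) -> None:
    """Write every planted assignment as TSV for downstream checking."""
    import os
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "bivalent_genes.tsv"), "w") as fh:
        fh.write("gene\n")
        for g in truth.bivalent_genes:
            fh.write(f"{g}\n")
    with open(os.path.join(outdir, "bivalent_domains.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tgene\n")
        for d in truth.bivalent_domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\n")
    truth.mark_status.rename_axis("gene").to_csv(
        os.path.join(outdir, "mark_status.tsv"), sep="\t")
    truth.de.to_csv(os.path.join(outdir, "de.tsv"), sep="\t")
    truth.gene_means.round(6).rename_axis("gene").to_csv(
        os.path.join(outdir, "gene_means.tsv"), sep="\t")
    truth.metabolites.to_csv(os.path.join(outdir, "metabolites.tsv"), sep="\t")
    with open(os.path.join(outdir, "state_path.tsv"), "w") as fh:
        fh.write("chrom\tbin\tstate\n")
        for chrom, path in truth.state_paths.items():
            for i, s in enumerate(path):
                fh.write(f"{chrom}\t{i}\t{int(s)}\n")
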