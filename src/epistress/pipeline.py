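"""Stage orchestration: simulate -> annotate -> states -> bivalent ->
expression -> dynamics, driven by one config, with deterministic reports.

Each stage reads only the declared files of the working directory and writes
its outputs under its own subdirectory; every JSON report carries the config
hash and seed, and no report contains timestamps, so a rerun with the same
config and inputs is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
import sys

import numpy as np
import pandas as pd
import yaml

from . import bivalency as bv
from . import chromatin_states as cs
from . import differential_dynamics as dd
from . import expression_integration as ei
from . import io_formats as io
from . import peak_annotation as pa
from . import synthetic_data as sd
from .genome_model import MARKS, build_feature_index

log = logging.getLogger("epistress")

STAGES = ("simulate", "annotate", "states", "bivalent", "expression", "dynamics")
GENE_MARKS = sd.GENE_MARKS

DEFAULT_THRESHOLDS = {
    "promoter_window": 2000,
    "bin_size": 200,
    "n_states": 10,
    "hmm_restarts": 2,
    "hmm_max_iter": 100,
    "hmm_tol": 1e-3,
    "decode_method": "posterior",
    "lfc_min": 1.0,
    "fdr_max": 0.05,
    "min_jaccard_stable": 0.25,
    "min_overlap_bp": 1,
    "breadth_threshold": 1.0,
    "n_random_genes": 10000,
    "n_perm": 200,
    "metabolite_filter": "results",
}


@dataclasses.dataclass
class RunConfig:
    """The single source of every threshold, window and seed."""

    outdir: str
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    thresholds: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        if outdir is not None:
            obj["outdir"] = outdir
        if seed is not None:
            obj["seed"] = seed
        if "outdir" not in obj:
            raise ValueError("config must provide outdir (or pass --outdir)")
        return cls(**obj)

    def config_hash(self) -> str:
        payload = {"seed": self.seed, "simulate": self.simulate,
                   "thresholds": self.thresholds}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _report(cfg: RunConfig, stage_dir: str, payload: dict) -> None:
    payload = dict(payload)
    payload["config_hash"] = cfg.config_hash()
    payload["seed"] = cfg.seed
    with open(os.path.join(stage_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")


def _require(cfg: RunConfig, stage: str, *names: str) -> list[str]:
    paths = []
    for name in names:
        path = os.path.join(cfg.outdir, name)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"stage '{stage}' needs {name!r}; run the producing stage first")
        paths.append(path)
    return paths


def _load_inputs(cfg: RunConfig, stage: str, peaks: bool = True):
    genome_path, genes_path = _require(cfg, stage, "genome.tsv", "genes.gff3")
    layout = io.read_genome(genome_path)
    genes = io.read_gff3(genes_path, layout)
    peak_sets = {}
    if peaks:
        for mark in MARKS:
            for cond in ("CK", "NaCl"):
                (path,) = _require(cfg, stage, f"peaks_{mark}_{cond}.bed")
                peak_sets[(mark, cond)] = io.read_bed(path, layout, mark=mark,
                                                      condition=cond)
    return layout, genes, peak_sets


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> None:
    sim_cfg = sd.SimConfig(seed=cfg.seed, **cfg.simulate)
    sd.simulate(sim_cfg, outdir=cfg.outdir)
    stage_dir = os.path.join(cfg.outdir, "simulate")
    os.makedirs(stage_dir, exist_ok=True)
    _report(cfg, stage_dir, {"stage": "simulate",
                             "n_genes": sim_cfg.n_genes,
                             "genome_bp": int(sum(sim_cfg.chrom_lengths))})


def stage_annotate(cfg: RunConfig) -> None:
    th = cfg.thresholds
    layout, genes, peak_sets = _load_inputs(cfg, "annotate")
    index = build_feature_index(genes, layout, th["promoter_window"])
    stage_dir = os.path.join(cfg.outdir, "annotate")
    os.makedirs(stage_dir, exist_ok=True)
    dist_rows, cov = [], {}
    marked = {}
    for (mark, cond), ps in sorted(peak_sets.items()):
        _, dist = pa.assign_peaks(ps, index)
        row = {"mark": mark, "condition": cond, "n_peaks": len(ps)}
        row.update(dist.fractions)
        dist_rows.append(row)
        cov[f"{mark}_{cond}"] = pa.genome_coverage(ps, layout)
        marked[(mark, cond)] = pa.marked_genes(ps, genes, layout, th["promoter_window"])
    pd.DataFrame(dist_rows).to_csv(os.path.join(stage_dir, "feature_distribution.tsv"),
                                   sep="\t", index=False, float_format="%.6g")
    with open(os.path.join(stage_dir, "marked_genes.tsv"), "w") as fh:
        fh.write("mark\tcondition\tgene\n")
        for (mark, cond), ms in sorted(marked.items()):
            for g in sorted(ms.genes):
                fh.write(f"{mark}\t{cond}\t{g}\n")
    venn = pa.multiway_venn([marked[(m, "CK")] for m in GENE_MARKS])
    with open(os.path.join(stage_dir, "venn_CK.tsv"), "w") as fh:
        fh.write("region\tcount\n")
        for key in sorted(venn, key=lambda k: (len(k), k)):
            fh.write("+".join(key) + f"\t{venn[key]}\n")
    hist_edges = [0, 200, 700, 1500, 5000, float("inf")]
    hist_rows = []
    for (mark, cond), ps in sorted(peak_sets.items()):
        counts = pa.peak_length_histogram(ps, hist_edges)
        hist_rows.append({"mark": mark, "condition": cond,
                          **{f"len_{hist_edges[i]}_{hist_edges[i+1]}": int(c)
                             for i, c in enumerate(counts)}})
    pd.DataFrame(hist_rows).to_csv(os.path.join(stage_dir, "peak_lengths.tsv"),
                                   sep="\t", index=False)
    profiles = {}
    for mark in GENE_MARKS:
        prof = pa.metagene_profile(peak_sets[(mark, "CK")], genes, layout)
        profiles[mark] = prof.values
    pd.DataFrame(profiles).rename_axis("bin").to_csv(
        os.path.join(stage_dir, "metagene_CK.tsv"), sep="\t", float_format="%.6g")
    _report(cfg, stage_dir, {
        "stage": "annotate",
        "genome_coverage": cov,
        "marked_gene_counts": {f"{m}_{c}": len(s.genes)
                               for (m, c), s in sorted(marked.items())},
    })


def stage_states(cfg: RunConfig) -> None:
    th = cfg.thresholds
    layout, genes, peak_sets = _load_inputs(cfg, "states")
    binned = cs.BinnedGenome(layout, th["bin_size"])
    X_ck = cs.binarize_marks({m: peak_sets[(m, "CK")] for m in MARKS}, binned, MARKS)
    X_na = cs.binarize_marks({m: peak_sets[(m, "NaCl")] for m in MARKS}, binned, MARKS)
    model = cs.fit_hmm(X_ck, K=th["n_states"], seed=cfg.stage_seed("states"),
                       n_restarts=th["hmm_restarts"], tol=th["hmm_tol"],
                       max_iter=th["hmm_max_iter"])
    seg_ck = cs.decode(X_ck, model, method=th["decode_method"])
    seg_na = cs.decode(X_na, model, method=th["decode_method"])
    stage_dir = os.path.join(cfg.outdir, "states")
    os.makedirs(stage_dir, exist_ok=True)
    model.to_json(os.path.join(stage_dir, "model.json"))
    seg_ck.to_bed(os.path.join(stage_dir, "segmentation_CK.bed"))
    seg_na.to_bed(os.path.join(stage_dir, "segmentation_NaCl.bed"))
    index = build_feature_index(genes, layout, th["promoter_window"])
    te_classes = None
    te_path = os.path.join(cfg.outdir, "te.bed")
    if os.path.exists(te_path):
        te_peaks = io.read_bed(te_path, layout)
        groups: dict[str, dict] = {}
        for p in te_peaks:
            groups.setdefault(p.name or "TE", {}).setdefault(p.chrom, []).append(
                (p.start, p.end))
        from . import _intervals as iv
        te_classes = {cls: {c: iv.merge(*iv.as_arrays(v)) for c, v in by.items()}
                      for cls, by in groups.items()}
    expr_means = None
    expr_path = os.path.join(cfg.outdir, "expression.tsv")
    if os.path.exists(expr_path):
        expr = io.read_expression_table(expr_path)
        expr_means = ei.condition_means(expr, "CK")
    summary = cs.annotate_states(seg_ck, index, te_classes, expr_means, genes,
                                 th["promoter_window"])
    summary.to_csv(os.path.join(stage_dir, "state_summary.tsv"), sep="\t",
                   float_format="%.6g")
    frac, table = cs.state_dynamics(seg_ck, seg_na)
    table.to_csv(os.path.join(stage_dir, "state_transitions.tsv"), sep="\t")
    _report(cfg, stage_dir, {"stage": "states", "K": model.K,
                             "log_likelihood": model.log_likelihood,
                             "dynamic_bin_fraction": frac})


def stage_bivalent(cfg: RunConfig) -> None:
    th = cfg.thresholds
    layout, genes, peak_sets = _load_inputs(cfg, "bivalent")
    ab_path, ba_path = _require(cfg, "bivalent", "rechip_ab.bed", "rechip_ba.bed")
    domains = bv.call_bivalent(peak_sets[("H3K9ac", "CK")],
                               peak_sets[("H3K27me3", "CK")],
                               genes=genes, layout=layout,
                               min_overlap_bp=th["min_overlap_bp"],
                               promoter_window=th["promoter_window"])
    rechip_ab = io.read_bed(ab_path, layout, mark="H3K27me3", condition="CK")
    rechip_ba = io.read_bed(ba_path, layout, mark="H3K9ac", condition="CK")
    validation = bv.validate_rechip(domains, rechip_ab, rechip_ba,
                                    th["min_overlap_bp"], genes, layout,
                                    th["promoter_window"])
    obs, pval = bv.permutation_null(peak_sets[("H3K9ac", "CK")],
                                    peak_sets[("H3K27me3", "CK")], layout,
                                    n_perm=th["n_perm"],
                                    seed=cfg.stage_seed("bivalent"),
                                    min_overlap_bp=th["min_overlap_bp"])
    stage_dir = os.path.join(cfg.outdir, "bivalent")
    os.makedirs(stage_dir, exist_ok=True)
    io.write_bed(domains.domains, os.path.join(stage_dir, "domains.bed"), layout)
    _report(cfg, stage_dir, {
        "stage": "bivalent",
        "n_domains": len(domains),
        "frac_peaks_H3K9ac": domains.frac_peaks_a,
        "frac_peaks_H3K27me3": domains.frac_peaks_b,
        "n_genes": len(domains.genes),
        "rechip": dataclasses.asdict(validation),
        "permutation": {"observed": obs, "pvalue": pval},
    })


def stage_expression(cfg: RunConfig) -> None:
    th = cfg.thresholds
    layout, genes, peak_sets = _load_inputs(cfg, "expression")
    (expr_path,) = _require(cfg, "expression", "expression.tsv")
    expr = io.read_expression_table(expr_path)
    cats = ei.categorize_expression(expr, "CK")
    means = ei.condition_means(expr, "CK")
    stage_dir = os.path.join(cfg.outdir, "expression")
    os.makedirs(stage_dir, exist_ok=True)
    cats.rename_axis("gene").to_csv(os.path.join(stage_dir, "categories_CK.tsv"), sep="\t")
    rows = []
    tests = {}
    for mark in GENE_MARKS:
        marked = pa.marked_genes(peak_sets[(mark, "CK")], genes, layout,
                                 th["promoter_window"])
        tab = ei.mark_by_category(marked, cats)
        for cat, r in tab.iterrows():
            rows.append({"mark": mark, "category": cat, "count": int(r["count"]),
                         "fraction": r["fraction"]})
        res = ei.rank_compare(means.loc[sorted(marked.genes)].to_numpy(),
                              means.to_numpy())
        tests[mark] = {"U": res.statistic, "pvalue": res.pvalue,
                       "median_marked": res.median_a, "median_all": res.median_b}
    pd.DataFrame(rows).to_csv(os.path.join(stage_dir, "mark_by_category.tsv"),
                              sep="\t", index=False, float_format="%.6g")
    breadth = ei.expression_breadth(expr, th["breadth_threshold"])
    breadth.rename_axis("gene").round(6).to_csv(
        os.path.join(stage_dir, "breadth.tsv"), sep="\t")
    random_panel = ei.sample_random_genes(list(expr.index), th["n_random_genes"],
                                          seed=cfg.stage_seed("expression"))
    with open(os.path.join(stage_dir, "random_genes.tsv"), "w") as fh:
        fh.write("gene\n")
        for g in sorted(random_panel):
            fh.write(f"{g}\n")
    _report(cfg, stage_dir, {"stage": "expression", "rank_tests": tests,
                             "category_counts": cats.value_counts().to_dict()})


def stage_dynamics(cfg: RunConfig) -> None:
    th = cfg.thresholds
    layout, genes, peak_sets = _load_inputs(cfg, "dynamics")
    (expr_path,) = _require(cfg, "dynamics", "expression.tsv")
    expr = io.read_expression_table(expr_path)
    de = dd.simple_de(expr)
    up, down = dd.call_de(de, th["lfc_min"], th["fdr_max"])
    dynamics = {}
    for mark in GENE_MARKS:
        dynamics[mark] = dd.mark_gain_loss(peak_sets[(mark, "CK")],
                                           peak_sets[(mark, "NaCl")], genes, layout,
                                           th["promoter_window"],
                                           th["min_jaccard_stable"])
    report = dd.concordance(up, down, dynamics)
    index = build_feature_index(genes, layout, th["promoter_window"])
    stage_dir = os.path.join(cfg.outdir, "dynamics")
    os.makedirs(stage_dir, exist_ok=True)
    de.round(6).to_csv(os.path.join(stage_dir, "de.tsv"), sep="\t")
    for mark, dyn in dynamics.items():
        dyn.round(6).to_csv(os.path.join(stage_dir, f"dynamics_{mark}.tsv"), sep="\t")
    with open(os.path.join(stage_dir, "classes.tsv"), "w") as fh:
        fh.write("class\tgene\n")
        for name, members in sorted(report.classes.items()):
            for g in sorted(members):
                fh.write(f"{name}\t{g}\n")
    prom_rates = {}
    for name, members in sorted(report.classes.items()):
        mark = name.split("-")[0]
        change = name.split("-")[1].split("/")[0]
        if change == "gain":
            changed = dd.condition_unique_peaks(peak_sets[(mark, "NaCl")],
                                                peak_sets[(mark, "CK")])
        else:
            changed = dd.condition_unique_peaks(peak_sets[(mark, "CK")],
                                                peak_sets[(mark, "NaCl")])
        pr = dd.promoter_rate(members, changed, index, genes, th["promoter_window"])
        prom_rates[name] = dataclasses.asdict(pr)
    ratios = {m: dynamics[m]["log_ratio"] for m in GENE_MARKS}
    corr = dd.fc_correlation(ratios, de["log2fc"])
    corr.to_csv(os.path.join(stage_dir, "fc_correlation.tsv"), sep="\t",
                index=False, float_format="%.6g")
    corr_s = dd.fc_correlation(ratios, de["log2fc"], method="spearman")
    corr_s.to_csv(os.path.join(stage_dir, "fc_correlation_spearman.tsv"), sep="\t",
                  index=False, float_format="%.6g")
    variability = {m: dd.variability_score(peak_sets[(m, "CK")], peak_sets[(m, "NaCl")])
                   for m in MARKS}
    metab_path = os.path.join(cfg.outdir, "metabolites.tsv")
    metab_summary = {}
    if os.path.exists(metab_path):
        tab = io.read_metabolite_table(metab_path)
        flt = dd.METABOLITE_FILTERS[th["metabolite_filter"]]
        result = dd.filter_metabolites(tab, **flt)
        for mode, (u, d) in result.items():
            metab_summary[mode] = {"up": len(u), "down": len(d)}
            with open(os.path.join(stage_dir, f"metabolites_{mode}.tsv"), "w") as fh:
                fh.write("id\tdirection\n")
                for mid in sorted(u):
                    fh.write(f"{mid}\tup\n")
                for mid in sorted(d):
                    fh.write(f"{mid}\tdown\n")
    _report(cfg, stage_dir, {
        "stage": "dynamics",
        "n_up": len(up), "n_down": len(down),
        "class_sizes": {k: len(v) for k, v in sorted(report.classes.items())},
        "up_coverage": report.up_coverage, "down_coverage": report.down_coverage,
        "promoter_rates": prom_rates,
        "correlations": {f"{r.var_a}~{r.var_b}": (None if not np.isfinite(r.r) else r.r)
                         for r in corr.itertuples()},
        "variability": variability,
        "metabolites": metab_summary,
    })


_STAGE_FN = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "states": stage_states,
    "bivalent": stage_bivalent,
    "expression": stage_expression,
    "dynamics": stage_dynamics,
}


def run(subcommand: str, cfg: RunConfig) -> None:
    """Run one stage or ``all`` in dependency order.

    A failing stage removes its partial outputs before the error propagates.
    """
    stages = list(STAGES) if subcommand == "all" else [subcommand]
    if any(s not in STAGES for s in stages):
        raise ValueError(f"unknown stage {subcommand!r}")
    os.makedirs(cfg.outdir, exist_ok=True)
    for stage in stages:
        log.info(json.dumps({"event": "stage_start", "stage": stage,
                             "config_hash": cfg.config_hash(), "seed": cfg.seed}))
        stage_dir = os.path.join(cfg.outdir, stage)
        try:
            _STAGE_FN[stage](cfg)
        except Exception:
            if os.path.isdir(stage_dir):
                shutil.rmtree(stage_dir, ignore_errors=True)
            log.error(json.dumps({"event": "stage_failed", "stage": stage}))
            raise
        log.info(json.dumps({"event": "stage_done", "stage": stage}))


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        '{"logger":"%(name)s","level":"%(levelname)s","event":%(message)s}'))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
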