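"""DE thresholds, mark gain/loss, concordance, promoter rates, correlations,
variability and the metabolite filter — hand truth tables and oracles."""

import numpy as np
import pandas as pd
import pytest

from epistress import differential_dynamics as dd
from epistress.genome_model import GeneModel, GenomeLayout, build_feature_index
from conftest import make_peaks


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "fdr"]).set_index("gene")


def test_call_de_truth_table():
    de = de_frame([
        ("a", 1.5, 0.001, 0.01),    # up
        ("b", 1.0, 0.001, 0.01),    # boundary |lfc| = 1 -> up
        ("c", -1.0, 0.001, 0.01),   # boundary -> down
        ("d", -3.0, 0.01, 0.05),    # FDR not < 0.05 -> neither
        ("e", 0.9, 0.0001, 0.001),  # below lfc -> neither
        ("f", -2.0, 0.001, 0.049),  # down
    ])
    up, down = dd.call_de(de)
    assert up == {"a", "b"} and down == {"c", "f"}


class TestSimpleDE:
    def frame(self, ck, na):
        cols = {f"CK_{i+1}": v for i, v in enumerate(np.array(ck).T)}
        cols.update({f"NaCl_{i+1}": v for i, v in enumerate(np.array(na).T)})
        return pd.DataFrame(cols).rename_axis("gene").rename(index=lambda i: f"g{i}")

    def test_identical_matrices_null(self):
        expr = self.frame([[1, 2, 3], [5, 5, 5]], [[1, 2, 3], [5, 5, 5]])
        de = dd.simple_de(expr)
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["pvalue"] == 1.0).all()

    def test_pseudocount_identity_at_zero(self):
        expr = self.frame([[0, 0]], [[0, 0]])
        de = dd.simple_de(expr, pseudocount=1.0)
        assert de["log2fc"].iloc[0] == 0.0

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(12)
        n = 1000
        ck = rng.lognormal(1, 0.4, size=(n, 4))
        na = rng.lognormal(1, 0.4, size=(n, 4))
        de = dd.simple_de(self.frame(ck, na))
        # BH at 5% on a pure null: expected false discoveries ~ Binomial-ish
        assert (de["fdr"] < 0.05).sum() <= 0.05 * n + 3 * np.sqrt(0.05 * n)


class TestGainLoss:
    layout = GenomeLayout(("c1",), (50_000,))
    gene = GeneModel("g", "c1", "+", 10_000, 13_000, exons=((10_000, 13_000),), cds=())

    def dyn(self, ck_pairs, na_pairs, **kw):
        ck = make_peaks(ck_pairs, mark="H3K9ac", condition="CK")
        na = make_peaks(na_pairs, mark="H3K9ac", condition="NaCl")
        return dd.mark_gain_loss(ck, na, [self.gene], self.layout, **kw)

    def test_gain_loss_absent_stable(self):
        window_peak = [("c1", 9000, 9600)]
        assert self.dyn([], window_peak).loc["g", "status"] == "gain"
        assert self.dyn(window_peak, []).loc["g", "status"] == "loss"
        assert self.dyn([], []).loc["g", "status"] == "absent"
        assert self.dyn(window_peak, window_peak).loc["g", "status"] == "stable"

    def test_replacement_below_jaccard_floor_uses_ratio_sign(self):
        # CK 400 bp replaced by a disjoint 100 bp: Jaccard 0, ratio < 0 -> loss
        d = self.dyn([("c1", 9000, 9400)], [("c1", 11_000, 11_100)])
        assert d.loc["g", "status"] == "loss"
        # the mirror replacement is a gain
        d = self.dyn([("c1", 11_000, 11_100)], [("c1", 9000, 9400)])
        assert d.loc["g", "status"] == "gain"

    def test_high_jaccard_is_stable(self):
        d = self.dyn([("c1", 9000, 9600)], [("c1", 9100, 9700)])
        # 500/700 shared -> Jaccard 0.71 >= 0.25
        assert d.loc["g", "status"] == "stable"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        ck_pairs = [("c1", int(s), int(s) + 300) for s in rng.integers(0, 49_000, 10)]
        na_pairs = [("c1", int(s), int(s) + 300) for s in rng.integers(0, 49_000, 10)]
        fwd = self.dyn(ck_pairs, na_pairs)
        rev = self.dyn(na_pairs, ck_pairs)
        swap = {"gain": "loss", "loss": "gain", "stable": "stable", "absent": "absent"}
        assert rev.loc["g", "status"] == swap[fwd.loc["g", "status"]]
        assert rev.loc["g", "log_ratio"] == pytest.approx(-fwd.loc["g", "log_ratio"])

    def test_mark_mismatch_rejected(self):
        ck = make_peaks([], mark="H3K9ac")
        na = make_peaks([], mark="H3K4me3")
        with pytest.raises(ValueError, match="mismatch"):
            dd.mark_gain_loss(ck, na, [self.gene], self.layout)


def test_concordance_classes_definition():
    dyn = {
        "H3K4me3": pd.DataFrame({"status": ["gain", "stable"]}, index=["a", "b"]),
        "H3K9ac": pd.DataFrame({"status": ["gain", "gain"]}, index=["a", "b"]),
        "H3K27me3": pd.DataFrame({"status": ["gain", "loss"]}, index=["a", "b"]),
    }
    rep = dd.concordance(frozenset(["a", "b"]), frozenset(), dyn)
    assert rep.classes["H3K4me3-gain/up"] == {"a"}
    assert rep.classes["H3K9ac-gain/up"] == {"a", "b"}
    # H3K27me3 gain on an up gene is discordant -> not in any class
    assert rep.classes["H3K27me3-loss/up"] == {"b"}
    assert rep.covered_up == {"a", "b"} and rep.up_coverage == 1.0


def test_promoter_rate_hand_counts():
    layout = GenomeLayout(("c1",), (100_000,))
    genes = [GeneModel(f"g{i}", "c1", "+", 10_000 * (i + 1), 10_000 * (i + 1) + 2000,
                       exons=((10_000 * (i + 1), 10_000 * (i + 1) + 2000),), cds=())
             for i in range(5)]
    index = build_feature_index(genes, layout, 2000)
    # 8 peaks anchored in promoters, 2 in gene bodies (coding_exon)
    pairs = []
    for i in range(4):
        tss = genes[i].tss
        pairs.append(("c1", tss - 900, tss - 500))     # promoter anchor
        pairs.append(("c1", tss - 1900, tss - 1500))   # promoter anchor
    pairs.append(("c1", genes[4].tss + 100, genes[4].tss + 500))
    pairs.append(("c1", genes[4].tss + 900, genes[4].tss + 1300))
    changed = make_peaks(pairs, mark="H3K9ac", condition="NaCl")
    rate = dd.promoter_rate(frozenset(g.gene_id for g in genes), changed, index,
                            genes, 2000)
    assert rate.n_changed_peaks == 10
    assert rate.peak_rate == pytest.approx(0.8)
    assert rate.gene_rate == pytest.approx(4 / 5)
    empty = dd.promoter_rate(frozenset(), changed, index, genes, 2000)
    assert empty.peak_rate is None


def test_condition_unique_peaks():
    a = make_peaks([("c1", 0, 100), ("c1", 500, 600)], mark="H3K9ac", condition="NaCl")
    b = make_peaks([("c1", 50, 80)], mark="H3K9ac", condition="CK")
    unique = dd.condition_unique_peaks(a, b)
    assert [(p.start, p.end) for p in unique] == [(500, 600)]


def test_fc_correlation_exact_lines():
    idx = [f"g{i}" for i in range(10)]
    x = pd.Series(np.arange(10, dtype=float), index=idx)
    ratios = {"H3K4me3": 2 * x, "H3K9ac": -x}
    corr = dd.fc_correlation(ratios, x)
    table = {(r.var_a, r.var_b): r.r for r in corr.itertuples()}
    assert table[("H3K4me3", "expression")] == pytest.approx(1.0)
    assert table[("H3K9ac", "expression")] == pytest.approx(-1.0)
    assert table[("H3K4me3", "H3K9ac")] == pytest.approx(-1.0)
    # constant vector -> missing
    corr2 = dd.fc_correlation({"H3K4me3": pd.Series(1.0, index=idx)}, x)
    assert np.isnan(corr2["r"].iloc[0])


def test_variability_score_bp_oracle():
    a = make_peaks([("c1", 0, 100)])
    b = make_peaks([("c1", 50, 150)])
    assert dd.variability_score(a, b) == pytest.approx(2 / 3)  # 1 - 50/150
    assert dd.variability_score(a, a) == 0.0
    c = make_peaks([("c1", 500, 600)])
    assert dd.variability_score(a, c) == 1.0
    with pytest.warns(UserWarning):
        assert dd.variability_score(make_peaks([]), make_peaks([])) == 0.0


def test_variability_matches_boolean_oracle_random():
    rng = np.random.default_rng(44)
    L = 100_000
    pairs_a = [("c1", int(s), int(s) + int(rng.integers(50, 800)))
               for s in rng.integers(0, L - 1000, 150)]
    pairs_b = [("c1", int(s), int(s) + int(rng.integers(50, 800)))
               for s in rng.integers(0, L - 1000, 150)]
    a, b = make_peaks(pairs_a), make_peaks(pairs_b)
    ma = np.zeros(L, dtype=bool)
    mb = np.zeros(L, dtype=bool)
    for _, s, e in pairs_a:
        ma[s:e] = True
    for _, s, e in pairs_b:
        mb[s:e] = True
    want = 1 - (ma & mb).sum() / (ma | mb).sum()
    assert dd.variability_score(a, b) == pytest.approx(want, abs=1e-12)


def test_filter_metabolites_truth_table():
    tab = pd.DataFrame({
        "ion_mode": ["pos"] * 6,
        "vip":    [1.3, 0.9, 1.5, 1.2, 1.0, 2.0],
        "fc":     [2.0, 3.0, 0.5, 1.2, 2.0, 0.3],
        "pvalue": [0.01, 0.001, 0.04, 0.01, 0.01, 0.06],
    }, index=[f"M{i}" for i in range(6)])
    up, down = dd.filter_metabolites(tab)["pos"]
    # M0 passes up; M1 fails VIP gate; M2 passes down; M3 FC in dead zone;
    # M4 VIP exactly 1.0 (strict) fails; M5 p >= 0.05 fails
    assert up == {"M0"} and down == {"M2"}
    # the stricter preset keeps all gates strict: FC exactly at a bound
    # (2.0 up, 0.5 down) is out
    strict_up, strict_down = dd.filter_metabolites(
        tab, **dd.METABOLITE_FILTERS["strict"])["pos"]
    assert strict_up == set() and strict_down == set()
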