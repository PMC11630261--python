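# Methods

`epistress` re-implements, as a tested library, the analysis layer of a
multi-mark plant stress epigenomics study: starting from called peaks for
four histone modifications (H3K4me3, H3K9ac, H3K27me3, H3K9me2) under a
control (CK) and a salt-stress (NaCl) condition, it partitions the genome
into features, learns chromatin states, calls bivalent H3K9ac–H3K27me3
domains with sequential-ChIP validation, and integrates per-gene mark
dynamics with expression and metabolite changes. All development and testing
run against a synthetic world with planted ground truth; nothing in the
package depends on downloading real data.

## Coordinates and the feature partition

All internal coordinates are 0-based half-open (BED convention); GFF3 input
is converted at the I/O boundary. The genome is partitioned exhaustively
into six labels — promoter, 5′ UTR, coding exon, 3′ UTR, intron,
intergenic — with overlapping claims resolved by a fixed priority in that
order (promoter strongest). The partition is realized as per-chromosome
label arrays painted in increasing priority, which makes the "every base
labeled exactly once" property trivially checkable and `classify_position`
an array lookup; this design targets desk-scale genomes (up to tens of Mb),
not a multi-Gb assembly.

Choices a user can change and their defaults:

- **Promoter window**: 2000 bp upstream of the TSS (strand-aware, clipped at
  chromosome edges). Plant analyses commonly use 1–2 kb; the window is a
  parameter everywhere it matters and reported alongside any quantity that
  depends on it.
- **Gene "marked" rule**: a gene is marked by a peak set when ≥1 bp of any
  peak overlaps its promoter ∪ gene-body window.
- **Peak→feature assignment**: one label per peak, taken at the summit when
  the peak caller reported one, else the midpoint. This matches
  single-category percentage reporting; a basepair-share alternative can be
  derived from the label arrays if needed.
- **Genes without an annotated CDS** contribute their exonic bases as coding
  exon, keeping the six-label scheme total.

## Metagene profiles

Profiles run from TSS−1 kb to TTS+2 kb: fixed 50-bp flank bins and a gene
body rescaled to 100 bins. Minus-strand genes are reversed so the axis is
always TSS→TTS. Flank bins that would fall off the chromosome, and
zero-width body bins of genes shorter than the bin count, are treated as
missing and excluded from the mean rather than zero-filled.

## Chromatin states

Mark presence is binarized on a fixed 200-bp grid, either by peak overlap
(≥1 bp) or by a Poisson upper tail on bin counts (bin is "on" when
P(X ≥ count) under the genome-wide mean rate falls below 1e−4). Short
terminal bins are kept and weighted like full bins.

The segmentation model is a hidden Markov model with independent Bernoulli
emissions per mark — each state is characterized by a per-mark presence
probability, the standard multi-mark chromatin-state formulation.
Chromosomes are independent observation sequences. Fitting is Baum–Welch
with per-position scaling constants (no underflow at ≥10⁶ bins), seeded
random restarts (Dirichlet start/transition draws with a mild persistence
bias, uniform(0.2, 0.8) emissions), and a hard internal assertion that the
log-likelihood never decreases across iterations; a fixed seed gives
bit-identical fits. Decoding is posterior-marginal argmax by default, with
Viterbi available. The forward/backward/Viterbi kernels are JIT-compiled
with numba.

State-number selection: fits for a K range report log-likelihood and
BIC = −2·LL + p·ln(T) with p = (K−1) + K(K−1) + K·M free parameters, and the
choice is left to the caller (BIC argmin as the suggested default). The
pipeline's `states` stage uses a fixed configurable K (default 10) rather
than scanning on every run; a scan over K = 8…20 is available through
`scan_state_number`.

Per-state annotation reports genome fraction, fold enrichment over the six
feature labels and over transposable-element classes
((state∩feature / state) ÷ (feature / genome)), and the mean expression of
genes whose promoter∪body overlaps the state. States absent from the genome
get missing enrichments, never zeros. Condition comparison counts 200-bp
bins whose decoded state differs and tabulates the K×K transition table.

## Bivalent domains and reChIP validation

A bivalent domain is a maximal run of bases covered by peaks of *both*
marks: merged connected components of pairwise intersections with a
configurable minimum pairwise overlap (default 1 bp, the most permissive
reading; a union-extent mode widens components to the contributing peaks).
Reported alongside: the fraction of each mark's peaks involved in ≥1 domain
and the genes covered (marked-gene rule on the domain set).

Sequential-ChIP validation counts a domain as supported when it overlaps
both reChIP directions by the minimum overlap; because "fraction
overlapping" is ambiguous, support is reported per domain, per basepair and
per covered gene. The both-direction fraction can never exceed either
single direction (asserted). A permutation null places the second mark's
peaks uniformly at random within chromosomes (lengths preserved) and uses
the add-one estimator p = (1 + #{perm ≥ obs}) / (n_perm + 1).

## Expression integration

Condition values are mean FPKM over replicates. Strata: none (= 0),
low (0, 1], mid (1, 10], high (> 10) — the boundary values 1 and 10 close
the lower stratum, making the map total and exclusive. Marked-versus-all
comparisons use the two-sided Wilcoxon rank-sum test: the exact null
distribution when both groups have ≤ 20 values and no ties, otherwise the
tie-corrected normal approximation; fully tied inputs return p = 1 with a
warning. Expression breadth is the fraction of samples with FPKM ≥ 1
(threshold configurable); the tau specificity index is provided as an
alternative summary. Random gene panels (default 10 000, clipped to the
universe with a warning) are seeded draws without replacement.

## Differential dynamics

- **DE calls**: up iff log2FC ≥ 1 and FDR < 0.05; down mirrored. The
  boundary |log2FC| = 1 is included, FDR = 0.05 excluded. The built-in
  `simple_de` computes log2FC on pseudocounted condition means
  (pseudocount 1 FPKM), p from a two-sample t on log2(FPKM+1), and BH FDR;
  it is a peak-level pipeline's light-weight stand-in, with zero-variance
  groups resolved to p = 1 (equal means) or p = 0 (the noise-free limit).
- **Mark gain/loss**: per-gene occupancy is the summed peak bp in the
  promoter∪body window. Unmarked→marked is gain, marked→unmarked loss,
  marked in neither absent. A gene marked in both conditions is stable only
  when the bp Jaccard of its window occupancy is ≥ 0.25; below the floor,
  the sign of log2((bp_NaCl+100)/(bp_CK+100)) decides gain vs loss, so a
  wholesale peak replacement is not misread as stability. Swapping the
  conditions swaps gain↔loss exactly.
- **Concordance classes**: the six biologically concordant pairings
  (active-mark gain/up, active-mark loss/down, H3K27me3 gain/down,
  H3K27me3 loss/up) as DEG∩status intersections, plus the fraction of DEGs
  covered by any class.
- **Promoter rates** over a class use condition-private peaks (zero overlap
  with the other condition) touching the class's genes; both the fraction
  of such peaks anchored in promoters and the fraction of class genes with
  a promoter-anchored changed peak are reported, since either reading is
  defensible.
- **Correlations** between per-mark occupancy log-ratios and the expression
  log2FC (and between marks) are Pearson by default with Spearman as an
  option; constant vectors yield missing r.
- **Variability** is 1 − bp-Jaccard of the merged CK/NaCl peak sets; two
  empty sets score 0 with a warning.
- **Metabolite filter**: up iff VIP > 1.0, FC > 1.5, p < 0.05; down iff
  FC < 0.667 with the same VIP/p gates; all gates strict. A stricter preset
  (FC 2.0 / 0.5) is available; it keeps strict inequalities, so values
  exactly on a bound are excluded.

## The synthetic world

The generator builds one coherent world per seed:

- **Genome**: 7 chromosomes totalling 10 Mb, 2000 genes (lognormal lengths,
  median 2 kb), 1–4 exons each with UTR-trimmed CDS. Inter-gene gaps are
  strand-aware so that promoter∪body windows are pairwise disjoint by
  construction — a planted per-gene edit can never bleed into a neighbour.
- **States→peaks**: a 6-state truth HMM (active promoter, transcription,
  bivalent, polycomb, heterochromatin, low) over 200-bp bins; mark bins are
  sampled from the state emissions and merged runs become peaks, which puts
  most peak lengths in the 200–700 bp band. The noise-free preset uses
  deterministic 0/1 emissions with no state carrying both H3K9ac and
  H3K27me3, so planted structure is the only structure.
- **Bivalency**: 35% of genes get both H3K9ac and H3K27me3 forced over a
  600-bp promoter core (the window is cleared first); reChIP sets are the
  realized bivalent domains with per-direction dropout (default 7% each, so
  both-direction support sits near 86%).
- **Expression**: lognormal baseline (log2 mean 2.2, sd 1.6; 8% silent),
  ×4 per active promoter mark, ÷2 under H3K27me3; bivalent genes keep the
  uncoupled intermediate regime with 3× replicate dispersion (their
  variable-expression signature). Five replicates per condition with
  lognormal noise (log2 sd 0.25).
- **Stress shift**: 150 up + 150 down genes drawn from genes with mean
  FPKM ≥ 5, |log2FC| = 2 + Exp(0.7) — large enough that the pseudocounted
  estimate clears the DEG threshold with margin. Each DE gene receives each
  concordant mark change with probability 0.7; a gain on an already-marked
  gene is planted as replacement at ≥4.2× occupancy (below the 0.25 Jaccard
  floor, hence an unambiguous gain). 2% per-gene per-mark uncoupled churn;
  optional unrecorded label noise for robustness experiments. This coupling
  yields |r| ≈ 0.4–0.65 mark–expression correlations with the expected sign
  pattern at n = 2000.
- **Metabolites**: 622 positive-mode and 537 negative-mode compounds with
  planted differential classes (139/51 and 158/39 up/down) and null rows
  engineered to fail at least one filter gate.

What the world does *not* emulate: read-level noise and mappability, peak
caller artifacts, inter-replicate ChIP variability (peaks are shared across
replicates by construction), genuine metabolite–gene mechanistic links, and
realistic repeat landscapes. Tests passing here demonstrate the statistics
and interval machinery, not robustness to alignment-level artifacts.

## Pipeline and determinism

Stages (`simulate`, `annotate`, `states`, `bivalent`, `expression`,
`dynamics`, or `all`) communicate only through files in the working
directory; a missing upstream file fails fast naming it, and a failing
stage removes its partial outputs. One YAML config is the single source of
thresholds; every report carries the config hash and seed and contains no
timestamps, so reruns with the same config are byte-identical. Per-stage
seeds are derived from the master seed by hashing, keeping stages
independent. The default problem sizes (10-Mb world, K = 10, 2 restarts,
100 EM iterations, 200 permutations) complete the full `all` run in well
under a minute on one CPU.

## Known limitations

- Per-base label arrays bound the practical genome size to what fits in
  memory (~1 byte/bp); fine for the intended synthetic/desk scale.
- `simple_de` is not a negative-binomial count model; it is a transparent
  stand-in operating on FPKM, adequate for planted lognormal worlds.
- The Wilcoxon exact mode requires tie-free pooled values; ties always fall
  back to the corrected normal approximation.
- HMM restarts use random initialization only; with very unbalanced states
  additional restarts may be needed for stable K scans.
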