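"""Chromatin-state segmentation: 200-bp binarization, a multivariate
Bernoulli-emission HMM fit by Baum-Welch, decoding, model scans and state
annotation.

The model follows the standard multi-mark segmentation scheme: each genomic
bin carries a binary presence call per histone mark; a hidden state emits the
marks independently, each with its own Bernoulli success probability, so a
state is characterized by its emission row (the per-mark "composition").
Chromosomes are treated as independent observation sequences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _hmm_kernels as hk
from . import _intervals as iv
from .genome_model import FEATURES, FeatureIndex, GenomeLayout, PeakSet

_EPS = 1e-10


@dataclass(frozen=True)
class BinnedGenome:
    """Fixed-width bin grid over a genome; the last bin of each chromosome
    may be short."""

    layout: GenomeLayout
    bin_size: int = 200

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(-(-l // self.bin_size) for l in self.layout.chrom_lengths)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins_per_chrom)

    @property
    def offsets(self) -> dict[str, int]:
        out, acc = {}, 0
        for name, n in zip(self.layout.chrom_names, self.n_bins_per_chrom):
            out[name] = acc
            acc += n
        return out

    def bin_interval(self, chrom: str, i: int) -> tuple[int, int]:
        L = self.layout.length(chrom)
        s = i * self.bin_size
        if not (0 <= s < L):
            raise IndexError(f"bin {i} outside {chrom}")
        return s, min(s + self.bin_size, L)


@dataclass
class BinarizedMatrix:
    """Bins x marks binary presence calls."""

    binned: BinnedGenome
    marks: tuple[str, ...]
    values: np.ndarray  # (total_bins, M) uint8
    source: str = "peak_overlap"

    def __post_init__(self):
        if self.values.shape != (self.binned.total_bins, len(self.marks)):
            raise ValueError("values shape does not match bins x marks")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binarized values must be 0/1")

    @property
    def lengths(self) -> tuple[int, ...]:
        return self.binned.n_bins_per_chrom


@dataclass
class HMMModel:
    """A fitted (or constructed) Bernoulli-emission HMM."""

    K: int
    start: np.ndarray        # (K,)
    transition: np.ndarray   # (K, K)
    emission: np.ndarray     # (K, M) Bernoulli success probabilities
    log_likelihood: float = np.nan
    seed: int | None = None
    n_iter: int = 0
    marks: tuple[str, ...] = ()

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if abs(self.start.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0,1]")

    @property
    def M(self) -> int:
        return self.emission.shape[1]

    def to_json(self, path) -> None:
        obj = {
            "K": self.K,
            "start": self.start.tolist(),
            "transition": self.transition.tolist(),
            "emission": self.emission.tolist(),
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "marks": list(self.marks),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "HMMModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(K=obj["K"], start=np.array(obj["start"]),
                   transition=np.array(obj["transition"]),
                   emission=np.array(obj["emission"]),
                   log_likelihood=obj["log_likelihood"], seed=obj["seed"],
                   n_iter=obj["n_iter"], marks=tuple(obj["marks"]))


@dataclass
class StateSegmentation:
    """Per-bin state labels in 1..K."""

    binned: BinnedGenome
    states: np.ndarray  # (total_bins,) int, 1-based
    K: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.states.shape != (self.binned.total_bins,):
            raise ValueError("state vector length does not match bin count")
        if self.states.min() < 1 or self.states.max() > self.K:
            raise ValueError("state labels out of range 1..K")

    def state_intervals(self, state: int) -> dict[str, iv.IntervalArrays]:
        """Merged bp intervals occupied by one state, per chromosome."""
        out = {}
        offsets = self.binned.offsets
        for chrom, n in zip(self.binned.layout.chrom_names, self.binned.n_bins_per_chrom):
            seg = self.states[offsets[chrom]:offsets[chrom] + n]
            idx = np.flatnonzero(seg == state)
            if idx.size == 0:
                continue
            bs = self.binned.bin_size
            L = self.binned.layout.length(chrom)
            starts = idx * bs
            ends = np.minimum(starts + bs, L)
            out[chrom] = iv.merge(starts.astype(np.int64), ends.astype(np.int64))
        return out

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            offsets = self.binned.offsets
            for chrom, n in zip(self.binned.layout.chrom_names, self.binned.n_bins_per_chrom):
                seg = self.states[offsets[chrom]:offsets[chrom] + n]
                bs = self.binned.bin_size
                L = self.binned.layout.length(chrom)
                run_start = 0
                for i in range(1, n + 1):
                    if i == n or seg[i] != seg[run_start]:
                        s = run_start * bs
                        e = min(i * bs, L)
                        fh.write(f"{chrom}\t{s}\t{e}\tCS{int(seg[run_start])}\n")
                        run_start = i


# ---------------------------------------------------------------------------
# binarization

def binarize(
    data,
    binned: BinnedGenome,
    method: str = "peak_overlap",
    p_threshold: float = 1e-4,
) -> np.ndarray:
    """One binary column over all bins.

    peak_overlap: bin = 1 iff >=1 bp of a peak overlaps the bin.
    poisson_signal: ``data`` is a per-bin count vector; bin = 1 iff the
    upper-tail Poisson probability P(X >= count) under the genome-wide mean
    rate is below ``p_threshold``.
    """
    if method == "peak_overlap":
        if not isinstance(data, PeakSet):
            raise TypeError("peak_overlap binarization requires a PeakSet")
        col = np.zeros(binned.total_bins, dtype=np.uint8)
        offsets = binned.offsets
        bs = binned.bin_size
        for p in data:
            off = offsets[p.chrom]
            first = p.start // bs
            last = (p.end - 1) // bs
            col[off + first:off + last + 1] = 1
        return col
    if method == "poisson_signal":
        counts = np.asarray(data, dtype=float)
        if counts.shape != (binned.total_bins,):
            raise ValueError("count vector length must equal total bins")
        mu = counts.mean()
        if mu == 0:
            warnings.warn("all-zero signal: binarized column is all zeros")
            return np.zeros(binned.total_bins, dtype=np.uint8)
        pvals = stats.poisson.sf(counts - 1, mu)  # P(X >= count)
        return (pvals < p_threshold).astype(np.uint8)
    raise ValueError(f"unknown binarization method {method!r}")


def binarize_marks(
    peak_sets: dict[str, PeakSet],
    binned: BinnedGenome,
    marks: tuple[str, ...] | None = None,
) -> BinarizedMatrix:
    """Stack per-mark peak-overlap columns into a BinarizedMatrix."""
    marks = tuple(marks or peak_sets.keys())
    cols = [binarize(peak_sets[m], binned, "peak_overlap") for m in marks]
    return BinarizedMatrix(binned=binned, marks=marks,
                           values=np.stack(cols, axis=1), source="peak_overlap")


# ---------------------------------------------------------------------------
# likelihood plumbing

def _emission_matrix(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Per-bin per-state emission likelihoods for independent Bernoulli marks."""
    Ec = np.clip(E, _EPS, 1 - _EPS)
    logB = X @ np.log(Ec).T + (1 - X) @ np.log1p(-Ec).T
    return np.exp(logB)


def _split(values: np.ndarray, lengths) -> list[np.ndarray]:
    out, pos = [], 0
    for n in lengths:
        out.append(values[pos:pos + n])
        pos += n
    return out


def _as_matrix(X) -> tuple[np.ndarray, list[int], tuple[str, ...]]:
    if isinstance(X, BinarizedMatrix):
        return X.values.astype(np.float64), list(X.lengths), X.marks
    arr = np.asarray(X, dtype=np.float64)
    return arr, [arr.shape[0]], ()


def forward_loglik(X, model: HMMModel, lengths=None) -> float:
    """Total forward log-likelihood over independent sequences."""
    arr, default_lengths, _ = _as_matrix(X)
    lengths = list(lengths) if lengths is not None else default_lengths
    B = _emission_matrix(arr, model.emission)
    ll = 0.0
    for seg in _split(B, lengths):
        if seg.shape[0]:
            ll += hk.forward_scaled(seg, model.start, model.transition)[0]
    return float(ll)


def posterior_marginals(X, model: HMMModel, lengths=None) -> np.ndarray:
    """Per-bin posterior state probabilities (rows sum to 1)."""
    arr, default_lengths, _ = _as_matrix(X)
    lengths = list(lengths) if lengths is not None else default_lengths
    B = _emission_matrix(arr, model.emission)
    out = []
    for seg in _split(B, lengths):
        if seg.shape[0] == 0:
            continue
        _, gamma, _, _ = hk.forward_backward(seg, model.start, model.transition)
        out.append(gamma)
    return np.vstack(out)


# ---------------------------------------------------------------------------
# fitting

def _init_params(K: int, M: int, rng: np.random.Generator):
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    A = A + np.eye(K)  # mild persistence bias in the start point
    A /= A.sum(axis=1, keepdims=True)
    E = rng.uniform(0.2, 0.8, size=(K, M))
    return pi, A, E


def fit_hmm(
    X,
    K: int,
    seed: int,
    n_restarts: int = 3,
    tol: float = 1e-4,
    max_iter: int = 500,
    lengths=None,
) -> HMMModel:
    """Baum-Welch for the independent-Bernoulli-emission HMM.

    Runs ``n_restarts`` seeded random initializations and keeps the best
    final log-likelihood.  The per-iteration log-likelihood is checked to be
    non-decreasing (up to round-off); a violation raises, as it signals a
    numerical defect rather than a modelling choice.  A fixed seed gives
    bit-identical results.
    """
    arr, default_lengths, marks = _as_matrix(X)
    lengths = list(lengths) if lengths is not None else default_lengths
    if K < 1:
        raise ValueError("K must be >= 1")
    if arr.shape[0] == 0:
        raise ValueError("empty observation matrix")
    M = arr.shape[1]
    if K > 2 ** M:
        warnings.warn(f"K={K} exceeds the {2 ** M} possible observation rows; "
                      "degenerate states are likely")

    segments = _split(arr, lengths)
    T = arr.shape[0]

    best = None
    master = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        pi, A, E = _init_params(K, M, master)
        prev_ll = -np.inf
        ll = prev_ll
        for it in range(1, max_iter + 1):
            B = _emission_matrix(arr, E)
            ll = 0.0
            gamma_acc = np.zeros((T, K))
            xi_acc = np.zeros((K, K))
            pi_acc = np.zeros(K)
            pos = 0
            for seg_x, n in zip(segments, lengths):
                if n == 0:
                    continue
                seg_ll, gamma, xi, g0 = hk.forward_backward(B[pos:pos + n], pi, A)
                ll += seg_ll
                gamma_acc[pos:pos + n] = gamma
                xi_acc += xi
                pi_acc += g0
                pos += n
            if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
                raise RuntimeError(
                    f"Baum-Welch log-likelihood decreased: {prev_ll} -> {ll}")
            converged = np.isfinite(prev_ll) and (ll - prev_ll) < tol
            # M step
            denom = gamma_acc.sum(axis=0)
            E = (gamma_acc.T @ arr) / denom[:, None]
            E = np.clip(E, 0.0, 1.0)
            rows = xi_acc.sum(axis=1)
            A = np.where(rows[:, None] > 0, xi_acc / np.maximum(rows[:, None], _EPS),
                         np.eye(K))
            A /= A.sum(axis=1, keepdims=True)
            pi = pi_acc / pi_acc.sum()
            prev_ll = ll
            if converged:
                break
        model = HMMModel(K=K, start=pi, transition=A, emission=E,
                         log_likelihood=float(ll), seed=seed, n_iter=it, marks=marks)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    # score with the final parameters so reported LL matches the model exactly
    best.log_likelihood = forward_loglik(arr, best, lengths)
    return best


def decode(X, model: HMMModel, method: str = "posterior", lengths=None) -> StateSegmentation:
    """Assign a state to every bin: posterior argmax or the Viterbi path."""
    arr, default_lengths, _ = _as_matrix(X)
    lengths = list(lengths) if lengths is not None else default_lengths
    if arr.shape[1] != model.M:
        raise ValueError("mark count of data and model differ")
    if method == "posterior":
        gamma = posterior_marginals(arr, model, lengths)
        states = gamma.argmax(axis=1) + 1
    elif method == "viterbi":
        Ec = np.clip(model.emission, _EPS, 1 - _EPS)
        logB = arr @ np.log(Ec).T + (1 - arr) @ np.log1p(-Ec).T
        logpi = np.log(np.maximum(model.start, _EPS))
        logA = np.log(np.maximum(model.transition, _EPS))
        parts = []
        for seg in _split(logB, lengths):
            if seg.shape[0]:
                path, _ = hk.viterbi_path(seg, logpi, logA)
                parts.append(path + 1)
        states = np.concatenate(parts)
    else:
        raise ValueError(f"unknown decode method {method!r}")
    if isinstance(X, BinarizedMatrix):
        return StateSegmentation(binned=X.binned, states=states.astype(np.int64),
                                 K=model.K, provenance={"method": method, "seed": model.seed})
    # bare-array input: wrap in a single synthetic chromosome grid
    layout = GenomeLayout(("seq",), (arr.shape[0],))
    binned = BinnedGenome(layout, bin_size=1)
    return StateSegmentation(binned=binned, states=states.astype(np.int64), K=model.K,
                             provenance={"method": method, "seed": model.seed})


def viterbi_logprob(X, model: HMMModel) -> float:
    """Log-probability of the Viterbi path of a single-sequence input."""
    arr, _, _ = _as_matrix(X)
    Ec = np.clip(model.emission, _EPS, 1 - _EPS)
    logB = arr @ np.log(Ec).T + (1 - arr) @ np.log1p(-Ec).T
    _, lp = hk.viterbi_path(logB, np.log(np.maximum(model.start, _EPS)),
                            np.log(np.maximum(model.transition, _EPS)))
    return float(lp)


def scan_state_number(X, k_range=range(8, 21), seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Fit one model per K and report log-likelihood and BIC.

    BIC = -2 LL + p ln(T) with p = (K-1) + K(K-1) + K M free parameters.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty K range")
    arr, default_lengths, _ = _as_matrix(X)
    T = arr.shape[0]
    M = arr.shape[1]
    rows = []
    for K in ks:
        model = fit_hmm(X, K=K, seed=seed, **fit_kwargs)
        p = (K - 1) + K * (K - 1) + K * M
        bic = -2.0 * model.log_likelihood + p * np.log(T)
        rows.append({"K": K, "loglik": model.log_likelihood, "n_params": p, "bic": bic})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation and dynamics

def annotate_states(
    seg: StateSegmentation,
    index: FeatureIndex | None = None,
    te_classes: dict[str, dict[str, iv.IntervalArrays]] | None = None,
    expr_means: pd.Series | None = None,
    genes=None,
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Per-state summary: genome fraction, feature/TE fold enrichment and
    mean expression of overlapping genes.

    Fold enrichment = (state∩feature bp / state bp) / (feature bp / genome bp).
    States absent from the genome get missing (NaN) enrichments, not zeros.
    """
    layout = seg.binned.layout
    genome_bp = layout.total_bp
    rows = []
    feat_bp = index.feature_bp() if index is not None else {}
    te_bp = {}
    if te_classes:
        te_bp = {cls: sum(iv.total_bp(s, e) for s, e in by.values())
                 for cls, by in te_classes.items()}
    for state in range(1, seg.K + 1):
        by_chrom = seg.state_intervals(state)
        state_bp = sum(iv.total_bp(s, e) for s, e in by_chrom.values())
        row = {"state": state, "bp": state_bp, "genome_fraction": state_bp / genome_bp}
        if index is not None:
            for feat, fbp in feat_bp.items():
                if state_bp == 0 or fbp == 0:
                    row[f"enrich_{feat}"] = np.nan
                    continue
                inter = 0
                for chrom, (s, e) in by_chrom.items():
                    arr = index.labels[chrom]
                    code = FEATURES.index(feat)
                    for a, b in zip(s, e):
                        inter += int((arr[a:b] == code).sum())
                row[f"enrich_{feat}"] = (inter / state_bp) / (fbp / genome_bp)
        if te_classes:
            for cls, by in te_classes.items():
                if state_bp == 0 or te_bp[cls] == 0:
                    row[f"te_{cls}"] = np.nan
                    continue
                inter = 0
                for chrom, (s, e) in by_chrom.items():
                    sb, eb = by.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
                    si, ei = iv.intersect(s, e, sb, eb)
                    inter += iv.total_bp(si, ei)
                row[f"te_{cls}"] = (inter / state_bp) / (te_bp[cls] / genome_bp)
        if expr_means is not None and genes is not None:
            vals = []
            for g in genes:
                if g.gene_id not in expr_means.index:
                    continue
                s, e = by_chrom.get(g.chrom, (None, None))
                if s is None:
                    continue
                ws, we = g.gene_window(promoter_window, layout.length(g.chrom))
                if iv.overlaps_point_set(s, e, ws, we):
                    vals.append(expr_means[g.gene_id])
            row["mean_expression"] = float(np.mean(vals)) if vals else np.nan
            row["n_genes"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")


def state_dynamics(segA: StateSegmentation, segB: StateSegmentation):
    """Fraction of bins whose state changed, plus the K x K transition table."""
    if segA.states.shape != segB.states.shape:
        raise ValueError("segmentations cover different bin grids")
    differs = segA.states != segB.states
    frac = float(differs.mean())
    K = max(segA.K, segB.K)
    table = np.zeros((K, K), dtype=np.int64)
    np.add.at(table, (segA.states - 1, segB.states - 1), 1)
    df = pd.DataFrame(table,
                      index=[f"CS{i}" for i in range(1, K + 1)],
                      columns=[f"CS{i}" for i in range(1, K + 1)])
    return frac, df
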