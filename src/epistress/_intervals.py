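"""Basepair-interval arithmetic on sorted numpy start/end arrays.

All coordinates are 0-based half-open.  Functions operate per chromosome on
parallel ``(starts, ends)`` int64 arrays; callers group by chromosome.
"""

from __future__ import annotations

import numpy as np

IntervalArrays = tuple[np.ndarray, np.ndarray]


def as_arrays(pairs) -> IntervalArrays:
    """Convert an iterable of (start, end) pairs to sorted int64 arrays."""
    if len(pairs) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    a = np.asarray(pairs, dtype=np.int64)
    order = np.lexsort((a[:, 1], a[:, 0]))
    a = a[order]
    return a[:, 0].copy(), a[:, 1].copy()


def merge(starts: np.ndarray, ends: np.ndarray, join_adjacent: bool = True) -> IntervalArrays:
    """Merge overlapping (and by default book-ended) intervals.

    Inputs need not be sorted.  Book-ended intervals ([a,b) and [b,c)) form a
    contiguous run of covered bases and are merged when ``join_adjacent``.
    """
    if starts.size == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    out_s = [s[0]]
    out_e = [e[0]]
    for i in range(1, s.size):
        gap_ok = s[i] <= out_e[-1] if join_adjacent else s[i] < out_e[-1]
        if gap_ok:
            if e[i] > out_e[-1]:
                out_e[-1] = e[i]
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_bp(starts: np.ndarray, ends: np.ndarray) -> int:
    """Covered bases of a *merged* interval set."""
    return int((ends - starts).sum())


def intersect(sa: np.ndarray, ea: np.ndarray, sb: np.ndarray, eb: np.ndarray) -> IntervalArrays:
    """Intersection of two *merged, sorted* interval sets.

    Returns the merged pieces covered by both sets (classic two-pointer sweep).
    """
    out_s, out_e = [], []
    i = j = 0
    while i < sa.size and j < sb.size:
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract(sa: np.ndarray, ea: np.ndarray, sb: np.ndarray, eb: np.ndarray) -> IntervalArrays:
    """Bases of merged set A not covered by merged set B."""
    out_s, out_e = [], []
    j = 0
    for s, e in zip(sa, ea):
        cur = s
        while j < sb.size and eb[j] <= cur:
            j += 1
        k = j
        while k < sb.size and sb[k] < e:
            if sb[k] > cur:
                out_s.append(cur)
                out_e.append(min(sb[k], e))
            cur = max(cur, eb[k])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlaps_point_set(starts: np.ndarray, ends: np.ndarray, qs: int, qe: int) -> bool:
    """True iff query [qs,qe) overlaps a *merged, sorted* interval set by >=1 bp."""
    if starts.size == 0 or qs >= qe:
        return False
    i = int(np.searchsorted(starts, qe, side="left"))
    return i > 0 and ends[i - 1] > qs


def overlap_bp_with(starts: np.ndarray, ends: np.ndarray, qs: int, qe: int) -> int:
    """Shared bases between query [qs,qe) and a merged, sorted interval set."""
    if starts.size == 0 or qs >= qe:
        return 0
    i = int(np.searchsorted(starts, qs, side="right")) - 1
    i = max(i, 0)
    bp = 0
    while i < starts.size and starts[i] < qe:
        lo = max(starts[i], qs)
        hi = min(ends[i], qe)
        if lo < hi:
            bp += hi - lo
        i += 1
    return int(bp)


def jaccard(a: dict, b: dict) -> tuple[float, int, int]:
    """Basepair Jaccard over per-chromosome merged interval dicts.

    ``a`` and ``b`` map chromosome -> (starts, ends) merged arrays.
    Returns (jaccard, intersection_bp, union_bp); both-empty gives (0, 0, 0).
    """
    inter = 0
    tot_a = 0
    tot_b = 0
    for chrom in set(a) | set(b):
        sa, ea = a.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        sb, eb = b.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        tot_a += total_bp(sa, ea)
        tot_b += total_bp(sb, eb)
        si, ei = intersect(sa, ea, sb, eb)
        inter += total_bp(si, ei)
    union = tot_a + tot_b - inter
    if union == 0:
        return 0.0, 0, 0
    return inter / union, inter, union
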