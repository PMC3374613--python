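"""Independent brute-force oracles used to check the implementation.

These deliberately re-derive each quantity from its definition by a
different route than the package takes (set enumeration, naive rescans,
full-matrix dynamic programming, per-base counting) and are kept free of
any mockmap internals beyond plain data.
"""
from __future__ import annotations

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -2, 3, 1
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_set(seq: str, k: int) -> set[str]:
    """Distinct canonical k-mers by explicit string enumeration."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if set(km) <= set("ACGT"):
            out.add(min(km, revcomp(km)))
    return out


def containment_similarity(seqs_a: list[str], seqs_b: list[str], k: int) -> float:
    sa: set[str] = set()
    for s in seqs_a:
        sa |= kmer_set(s, k)
    sb: set[str] = set()
    for s in seqs_b:
        sb |= kmer_set(s, k)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def sw_score(read: str, ref: str) -> int:
    """Best local alignment score by full-matrix dynamic programming.

    Row-vectorised Gotoh recurrence; the horizontal gap term uses the
    running-maximum identity max_{j'<j} (H[j'] - open - ext*(j-j'-1)).
    """
    enc = {b: i for i, b in enumerate("ACGT")}
    r = np.array([enc.get(b, 4) for b in read], dtype=np.int16)
    t = np.array([enc.get(b, 4) for b in ref], dtype=np.int16)
    w = len(t)
    neg = -(10**8)
    H_prev = np.zeros(w + 1, dtype=np.int64)
    F_prev = np.full(w + 1, neg, dtype=np.int64)
    ar = np.arange(w + 1, dtype=np.int64)
    best = 0
    for i in range(len(r)):
        F_row = np.maximum(H_prev - GAP_OPEN, F_prev - GAP_EXT)
        s = np.where((t == r[i]) & (t < 4), MATCH, MISMATCH)
        H0 = np.zeros(w + 1, dtype=np.int64)
        H0[1:] = np.maximum(np.maximum(H_prev[:-1] + s, F_row[1:]), 0)
        P = np.maximum.accumulate(H0 + ar)
        E = np.full(w + 1, neg, dtype=np.int64)
        # gap of length g costs GAP_OPEN + GAP_EXT*(g-1)
        E[1:] = P[:-1] - GAP_EXT * ar[1:] - (GAP_OPEN - GAP_EXT)
        H = np.maximum(H0, E)
        best = max(best, int(H.max()))
        H_prev, F_prev = H, F_row
    return best


def sw_best_score_both_strands(read: str, refs: list[str]) -> int:
    return max(
        max(sw_score(read, ref), sw_score(revcomp(read), ref)) for ref in refs
    )


def dust_mask_naive(seq: str, window: int = 64, level: float = 2.0) -> list[tuple[int, int]]:
    """Naive window-rescan DUST: recount every triplet of every window."""
    n = len(seq)
    seq = seq.upper()
    if n < 3:
        return []
    w = min(window, n)
    flagged = []
    for start in range(0, n - w + 1):
        counts: dict[str, int] = {}
        for i in range(start, start + w - 2):
            trip = seq[i : i + 3]
            if set(trip) <= set("ACGT"):
                counts[trip] = counts.get(trip, 0) + 1
        L = sum(counts.values())
        if L > 1:
            score = sum(c * (c - 1) / 2 for c in counts.values()) / (L - 1)
            if score > level:
                flagged.append((start, start + w))
    for i, b in enumerate(seq):
        if b not in "ACGT":
            flagged.append((i, i + 1))
    flagged.sort()
    merged: list[tuple[int, int]] = []
    for s, e in flagged:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage_naive(
    spans_by_seq: dict[str, list[tuple[int, int]]], seq_lengths: dict[str, int]
) -> dict[str, tuple[int, int]]:
    """(covered_bases, total_depth) per sequence by per-base counting."""
    out = {}
    for sid, length in seq_lengths.items():
        arr = np.zeros(length, dtype=np.int64)
        for s, e in spans_by_seq.get(sid, []):
            for p in range(s, e):
                arr[p] += 1
        out[sid] = (int((arr > 0).sum()), int(arr.sum()))
    return out


def spearman_naive(x, y) -> float:
    """Average ranks, then the Pearson correlation of the ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
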