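"""DUST-style low-complexity masking and read filtering with pair orphaning.

The classic DUST statistic scores a window by how skewed its trinucleotide
composition is: S(w) = sum_t c_t(c_t-1)/2 / (L-1), where c_t counts each
overlapping triplet and L is the number of counted triplets. Windows whose
score exceeds the level threshold are masked wholesale; overlapping masked
windows merge. Triplets containing N are not counted, and N bases are
masked unconditionally. A read is removed when its masked fraction exceeds
a cutoff; when exactly one mate of a pair is removed, the survivor is
orphaned into the fragment set so it can still be mapped.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .reads import ReadPair, ReadRecord


@dataclass
class MaskResult:
    read_id: str
    masked_intervals: list[tuple[int, int]]  # sorted, non-overlapping, half-open
    masked_fraction: float


_TRIPLET_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    out = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def dust_mask(
    sequence: str, read_id: str = "", window: int = 64, level: float = 2.0
) -> MaskResult:
    """Mask low-complexity spans of one read with the DUST triplet statistic.

    Windows slide by one base; the counts and the numerator
    sum c_t(c_t-1)/2 are updated incrementally so each step is O(1).
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    n = len(sequence)
    if n < 3:
        return MaskResult(read_id, [], 0.0)

    # triplet code per position, -1 when the triplet touches a non-ACGT base
    codes: list[int] = []
    vals = [_TRIPLET_BASE.get(b, -1) for b in sequence.upper()]
    for i in range(n - 2):
        a, b, c = vals[i], vals[i + 1], vals[i + 2]
        codes.append(-1 if (a < 0 or b < 0 or c < 0) else a * 16 + b * 4 + c)

    w = min(window, n)
    n_trip_full = w - 2  # triplets per full window
    counts = [0] * 64
    numer = 0  # sum c_t (c_t - 1) / 2
    valid = 0
    flagged: list[tuple[int, int]] = []

    def add(code: int) -> None:
        nonlocal numer, valid
        if code >= 0:
            numer += counts[code]
            counts[code] += 1
            valid += 1

    def remove(code: int) -> None:
        nonlocal numer, valid
        if code >= 0:
            counts[code] -= 1
            numer -= counts[code]
            valid -= 1

    for j in range(n_trip_full):
        add(codes[j])
    for start in range(0, n - w + 1):
        if start > 0:
            remove(codes[start - 1])
            add(codes[start + n_trip_full - 1])
        if valid > 1 and numer / (valid - 1) > level:
            flagged.append((start, start + w))

    # N runs are always masked
    for i, b in enumerate(sequence.upper()):
        if b not in _TRIPLET_BASE:
            flagged.append((i, i + 1))

    merged = _merge(flagged)
    masked = sum(e - s for s, e in merged)
    return MaskResult(read_id, merged, masked / n if n else 0.0)


def filter_reads(
    pairs: Sequence[ReadPair],
    fragments: Sequence[ReadRecord],
    max_masked_fraction: float = 0.5,
    window: int = 64,
    level: float = 2.0,
) -> tuple[list[ReadPair], list[ReadRecord], list[str]]:
    """Drop low-complexity reads; orphan surviving mates into the fragment set.

    Returns (kept_pairs, kept_fragments, removed_read_ids); kept fragments
    include orphans appended after the surviving input fragments, input
    order preserved within each group.
    """
    if not (0 < max_masked_fraction <= 1):
        raise ValueError("max_masked_fraction must be in (0, 1]")

    def bad(read: ReadRecord) -> bool:
        # a read with no callable base can never align, whatever the cutoff
        if not any(b in _TRIPLET_BASE for b in read.seq.upper()):
            return True
        mr = dust_mask(read.seq, read.id, window=window, level=level)
        return mr.masked_fraction > max_masked_fraction

    kept_pairs: list[ReadPair] = []
    orphans: list[ReadRecord] = []
    removed: list[str] = []
    for p in pairs:
        bad1, bad2 = bad(p.r1), bad(p.r2)
        if not bad1 and not bad2:
            kept_pairs.append(p)
        elif bad1 and bad2:
            removed.extend([p.r1.id, p.r2.id])
        elif bad1:
            removed.append(p.r1.id)
            orphans.append(p.r2)
        else:
            removed.append(p.r2.id)
            orphans.append(p.r1)

    kept_fragments: list[ReadRecord] = []
    for f in fragments:
        if bad(f):
            removed.append(f.id)
        else:
            kept_fragments.append(f)
    kept_fragments.extend(orphans)
    return kept_pairs, kept_fragments, removed


def write_removed_log(
    removed_ids: Sequence[str], masks: dict[str, MaskResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmasked_fraction\n")
        for rid in removed_ids:
            frac = masks[rid].masked_fraction if rid in masks else float("nan")
            fh.write(f"{rid}\t{frac:.4f}\n")
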