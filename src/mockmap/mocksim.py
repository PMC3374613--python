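"""Synthetic mock-community read simulation with per-read ground truth.

Emulates a defined mixture of strains sequenced as short paired-end reads:
each fragment is drawn from a strain with probability proportional to
concentration x genome length (shotgun sequencing samples DNA mass, not
cells), placed uniformly on the genome with an insert length uniform in a
configured range, and read from both ends in forward/reverse orientation.
Substitution errors are i.i.d. per base and never reproduce the original
base. Every read carries a truth label (source strain, sequence, 0-based
start of the read's own span, strand) so downstream mapping fates can be
scored exactly. Identical seeds give byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._kmers import decode, encode
from .reads import ReadPair, ReadRecord, revcomp
from .refdb import ReferenceDB


@dataclass
class CommunitySpec:
    """Composition and sequencing geometry of a simulated community."""

    members: list[tuple[str, float]]  # (strain prefix, relative concentration)
    n_pairs: int
    n_fragments: int = 0
    read_length: int = 100
    insert_range: tuple[int, int] = (180, 250)
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.members or all(c <= 0 for _, c in self.members):
            raise ValueError("community must have at least one member with concentration > 0")
        if any(c < 0 for _, c in self.members):
            raise ValueError("concentrations must be >= 0")
        lo, hi = self.insert_range
        if hi < lo:
            raise ValueError("insert_max must be >= insert_min")
        if lo < 1:
            raise ValueError("insert_min must be >= 1")


@dataclass
class TruthRow:
    prefix: str
    sequence_id: str
    start: int  # 0-based start of this read's span on the forward strand
    strand: str  # '+' or '-'


@dataclass
class SimResult:
    pairs: list[ReadPair]
    fragments: list[ReadRecord]
    truth: dict[str, TruthRow]


def _apply_substitutions(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    mask = rng.random(codes.shape) < rate
    if not mask.any():
        return codes
    out = codes.copy()
    shift = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shift) % 4
    return out


def simulate_community(db: ReferenceDB, spec: CommunitySpec) -> SimResult:
    """Generate paired-end reads, fragment reads and a truth table."""
    rng = np.random.default_rng(spec.seed)
    insert_min, insert_max = spec.insert_range
    rl = spec.read_length

    # one sampling slot per (strain, sequence) long enough to hold an insert
    slot_seq: list[tuple[str, str, np.ndarray]] = []  # (prefix, seq_id, codes)
    weights: list[float] = []
    for prefix, conc in spec.members:
        strain = db.get_strain(prefix)  # raises if absent
        if conc == 0:
            continue
        usable = [
            sid for sid in strain.sequence_ids if len(db.sequences[sid]) >= insert_max
        ]
        if not usable:
            raise ValueError(
                f"strain {prefix!r} has no sequence of length >= insert_max ({insert_max})"
            )
        for sid in usable:
            seq = db.sequences[sid]
            slot_seq.append((prefix, sid, encode(seq)))
            weights.append(conc * len(seq))
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()

    pairs: list[ReadPair] = []
    fragments: list[ReadRecord] = []
    truth: dict[str, TruthRow] = {}

    slot_idx = rng.choice(len(slot_seq), size=spec.n_pairs, p=p)
    inserts = rng.integers(insert_min, insert_max + 1, size=spec.n_pairs)
    u_start = rng.random(spec.n_pairs)
    flip = rng.random(spec.n_pairs) < 0.5
    for i in range(spec.n_pairs):
        prefix, sid, codes = slot_seq[slot_idx[i]]
        ins = int(inserts[i])
        rl_eff = min(rl, ins)  # a read cannot run past its fragment
        start = int(u_start[i] * (len(codes) - ins + 1))
        frag = codes[start : start + ins]
        fwd = frag[:rl_eff]
        rev = frag[ins - rl_eff :][::-1]
        rev = np.where(rev < 4, 3 - rev, rev).astype(np.uint8)
        base = f"sim{i:07d}"
        if not flip[i]:
            r1_codes, r1_start, r1_strand = fwd, start, "+"
            r2_codes, r2_start, r2_strand = rev, start + ins - rl_eff, "-"
        else:
            r1_codes, r1_start, r1_strand = rev, start + ins - rl_eff, "-"
            r2_codes, r2_start, r2_strand = fwd, start, "+"
        r1_codes = _apply_substitutions(r1_codes, spec.substitution_rate, rng)
        r2_codes = _apply_substitutions(r2_codes, spec.substitution_rate, rng)
        r1 = ReadRecord(id=base + "/1", seq=decode(r1_codes), mate=1)
        r2 = ReadRecord(id=base + "/2", seq=decode(r2_codes), mate=2)
        pairs.append(ReadPair(r1, r2))
        truth[r1.id] = TruthRow(prefix, sid, r1_start, r1_strand)
        truth[r2.id] = TruthRow(prefix, sid, r2_start, r2_strand)

    if spec.n_fragments:
        slot_idx = rng.choice(len(slot_seq), size=spec.n_fragments, p=p)
        u_start = rng.random(spec.n_fragments)
        neg = rng.random(spec.n_fragments) < 0.5
        for i in range(spec.n_fragments):
            prefix, sid, codes = slot_seq[slot_idx[i]]
            start = int(u_start[i] * (len(codes) - rl + 1))
            rcodes = codes[start : start + rl]
            strand = "+"
            if neg[i]:
                rcodes = np.where(rcodes[::-1] < 4, 3 - rcodes[::-1], rcodes[::-1]).astype(np.uint8)
                strand = "-"
            rcodes = _apply_substitutions(rcodes, spec.substitution_rate, rng)
            rec = ReadRecord(id=f"frag{i:07d}", seq=decode(rcodes), mate=0)
            fragments.append(rec)
            truth[rec.id] = TruthRow(prefix, sid, start, strand)

    return SimResult(pairs=pairs, fragments=fragments, truth=truth)


def inject_low_complexity(
    reads: Sequence[ReadRecord], fraction: float, seed: int
) -> list[ReadRecord]:
    """Replace a seeded random subset of reads with low-complexity repeats.

    ``round(fraction * n)`` reads have their sequence swapped for a
    homopolymer or dinucleotide repeat of equal length (screening-module
    test fixture). Order and read count are preserved.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    n = len(reads)
    n_alter = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=n_alter, replace=False).tolist()) if n_alter else set()
    patterns = ["A", "T", "G", "C", "AT", "CA", "GT", "CG"]
    out: list[ReadRecord] = []
    for i, r in enumerate(reads):
        if i in chosen:
            pat = patterns[int(rng.integers(len(patterns)))]
            seq = (pat * (len(r.seq) // len(pat) + 1))[: len(r.seq)]
            out.append(ReadRecord(id=r.id, seq=seq, qual=r.qual, mate=r.mate))
        else:
            out.append(r)
    return out


def write_truth(truth: dict[str, TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tprefix\tsequence_id\tstart\tstrand\n")
        for rid in truth:
            t = truth[rid]
            fh.write(f"{rid}\t{t.prefix}\t{t.sequence_id}\t{t.start}\t{t.strand}\n")


def read_truth(path: str | Path) -> dict[str, TruthRow]:
    truth: dict[str, TruthRow] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, prefix, sid, start, strand = line.rstrip("\n").split("\t")
            truth[rid] = TruthRow(prefix, sid, int(start), strand)
    return truth
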