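"""Seed-and-extend short-read mapper with similarity / length-fraction
filters, plus SAM import/export.

The mapper indexes reference k-mers (default k=16), collects candidate
diagonals for both read orientations, and extends each candidate locus with
a local dynamic-programming alignment restricted to a reference window
around the seeded diagonal — equivalent to a banded alignment whose band
half-width scales with the similarity filter, so no alignment passing the
filters can be clipped by the window. Alignments failing either filter
(identity below ``min_similarity``, or aligned query fraction below
``min_length_fraction``) are discarded; all surviving placements tied at
the maximal score form the read's HitSet. Tie resolution is deliberately
left to the resolution module.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from ._kmers import encode, kmer_codes
from ._sw import GAP_EXT, GAP_OPEN, MATCH, MISMATCH, align_window, collect_diagonals
from .reads import ReadPair, ReadRecord, revcomp
from .refdb import ReferenceDB


@dataclass
class Alignment:
    """One placement of a read on the reference (0-based half-open)."""

    read_id: str
    sequence_id: str
    ref_start: int
    ref_end: int
    strand: str
    score: int
    matches: int
    columns: int  # matches + mismatches + gap columns
    query_aligned: int  # aligned query bases
    read_length: int
    cigar: str

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def query_aligned_fraction(self) -> float:
        return self.query_aligned / self.read_length if self.read_length else 0.0


@dataclass
class HitSet:
    """All equally-best placements of one read (empty when unmapped)."""

    read_id: str
    best_score: int | None = None
    hits: list[Alignment] = field(default_factory=list)
    suppressed_count: int = 0

    def __bool__(self) -> bool:
        return bool(self.hits)


@dataclass
class SeedIndex:
    k: int
    max_seed_occupancy: int
    seq_ids: list[str]
    seq_starts: np.ndarray  # len(seq_ids)+1, global offsets into concat
    concat: np.ndarray  # uint8 codes of all sequences back to back
    uniq: np.ndarray  # sorted distinct k-mer codes kept after occupancy cut
    bounds: np.ndarray  # len(uniq)+1 offsets into positions
    positions: np.ndarray  # global k-mer start positions grouped by code


def build_index(
    db: ReferenceDB, k: int = 16, max_seed_occupancy: int = 1024
) -> SeedIndex:
    """Index every forward-strand reference k-mer below the occupancy cutoff."""
    if k < 11:
        raise ValueError("seed length k must be >= 11")
    seq_ids: list[str] = []
    chunks: list[np.ndarray] = []
    starts = [0]
    kmer_chunks: list[np.ndarray] = []
    pos_chunks: list[np.ndarray] = []
    for strain in db.strains:
        for sid in strain.sequence_ids:
            codes = encode(db.sequences[sid])
            off = starts[-1]
            seq_ids.append(sid)
            chunks.append(codes)
            starts.append(off + len(codes))
            kc, valid = kmer_codes(codes, k)
            idx = np.flatnonzero(valid)
            kmer_chunks.append(kc[idx])
            pos_chunks.append(idx.astype(np.int64) + off)
    concat = (
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
    )
    if kmer_chunks and sum(len(c) for c in kmer_chunks):
        kall = np.concatenate(kmer_chunks)
        pall = np.concatenate(pos_chunks)
        order = np.argsort(kall, kind="stable")
        ks, ps = kall[order], pall[order]
        uniq, counts = np.unique(ks, return_counts=True)
        keep = counts <= max_seed_occupancy
        entry_keep = np.repeat(keep, counts)
        ps = ps[entry_keep]
        uniq = uniq[keep]
        bounds = np.concatenate(
            [np.zeros(1, dtype=np.int64), np.cumsum(counts[keep])]
        )
    else:
        uniq = np.empty(0, dtype=np.uint64)
        bounds = np.zeros(1, dtype=np.int64)
        ps = np.empty(0, dtype=np.int64)
    return SeedIndex(
        k=k,
        max_seed_occupancy=max_seed_occupancy,
        seq_ids=seq_ids,
        seq_starts=np.asarray(starts, dtype=np.int64),
        concat=concat,
        uniq=uniq,
        bounds=bounds,
        positions=ps,
    )


def band_half_width(read_length: int, min_similarity: float) -> int:
    """Window slack guaranteeing no filter-passing alignment is clipped."""
    return int(math.ceil(read_length * (1.0 - min_similarity))) + 2


def _candidate_windows(
    oriented: np.ndarray, index: SeedIndex, hw: int
) -> list[tuple[int, int, int]]:
    """Seeded reference windows for one read orientation.

    Returns (seq_index, window_start, window_end) globals, one per cluster
    of nearby seed diagonals.
    """
    m = len(oriented)
    if index.uniq.size == 0:
        return []
    alld = collect_diagonals(
        oriented, index.k, index.uniq, index.bounds, index.positions
    )
    if alld.size == 0:
        return []
    windows: list[tuple[int, int, int]] = []
    cluster_start = 0
    for t in range(1, len(alld) + 1):
        if t == len(alld) or alld[t] - alld[t - 1] > hw:
            dlo = int(alld[cluster_start])
            dhi = int(alld[t - 1])
            rep = (dlo + dhi) // 2 + m // 2  # a position inside the alignment
            si = int(np.searchsorted(index.seq_starts, rep, side="right")) - 1
            si = max(0, min(si, len(index.seq_ids) - 1))
            ws = max(int(index.seq_starts[si]), dlo - hw)
            we = min(int(index.seq_starts[si + 1]), dhi + m + hw)
            if we > ws:
                windows.append((si, ws, we))
            cluster_start = t
    return windows


_OP_CHARS = "MID"


def _extend(
    read_id: str,
    oriented: np.ndarray,
    strand: str,
    index: SeedIndex,
    hw: int,
) -> list[Alignment]:
    out: list[Alignment] = []
    m = len(oriented)
    for si, ws, we in _candidate_windows(oriented, index, hw):
        (score, qs, qe, rs, re, matches, columns, ops, lens, n_ops) = align_window(
            oriented, index.concat[ws:we]
        )
        if score <= 0 or n_ops == 0:
            continue
        parts = []
        if qs > 0:
            parts.append(f"{qs}S")
        for t in range(n_ops):
            parts.append(f"{lens[t]}{_OP_CHARS[ops[t]]}")
        if m - qe > 0:
            parts.append(f"{m - qe}S")
        seq_off = int(index.seq_starts[si])
        out.append(
            Alignment(
                read_id=read_id,
                sequence_id=index.seq_ids[si],
                ref_start=ws - seq_off + int(rs),
                ref_end=ws - seq_off + int(re),
                strand=strand,
                score=int(score),
                matches=int(matches),
                columns=int(columns),
                query_aligned=int(qe - qs),
                read_length=m,
                cigar="".join(parts),
            )
        )
    return out


def map_read(
    read: ReadRecord,
    index: SeedIndex,
    db: ReferenceDB,
    min_length_fraction: float = 0.75,
    min_similarity: float = 0.80,
) -> HitSet:
    """Map one read, returning all equally-best filter-passing placements."""
    if not (0 < min_length_fraction <= 1 and 0 < min_similarity <= 1):
        raise ValueError("filters must be in (0, 1]")
    if len(read.seq) < index.k:
        warnings.warn(f"read {read.id} shorter than seed length; unmapped")
        return HitSet(read_id=read.id)
    hw = band_half_width(len(read.seq), min_similarity)
    fwd = encode(read.seq)
    rev = encode(revcomp(read.seq))
    candidates = _extend(read.id, fwd, "+", index, hw) + _extend(
        read.id, rev, "-", index, hw
    )
    survivors = [
        a
        for a in candidates
        if a.identity >= min_similarity
        and a.query_aligned_fraction >= min_length_fraction
    ]
    # collapse duplicate loci, keeping the best-scoring representative
    by_locus: dict[tuple[str, int, str], Alignment] = {}
    for a in survivors:
        key = (a.sequence_id, a.ref_start, a.strand)
        if key not in by_locus or a.score > by_locus[key].score:
            by_locus[key] = a
    survivors = list(by_locus.values())
    if not survivors:
        return HitSet(read_id=read.id)
    best = max(a.score for a in survivors)
    hits = [a for a in survivors if a.score == best]
    hits.sort(key=lambda a: (a.sequence_id, a.ref_start, a.strand))
    return HitSet(
        read_id=read.id,
        best_score=best,
        hits=hits,
        suppressed_count=len(survivors) - len(hits),
    )


def _is_proper(a: Alignment, b: Alignment, insert_range: tuple[int, int]) -> bool:
    if a.sequence_id != b.sequence_id or a.strand == b.strand:
        return False
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    if plus.ref_start > minus.ref_start:
        return False
    span = minus.ref_end - plus.ref_start
    return insert_range[0] <= span <= insert_range[1]


def map_pairs(
    pairs: Sequence[ReadPair],
    fragments: Sequence[ReadRecord],
    index: SeedIndex,
    db: ReferenceDB,
    min_length_fraction: float = 0.75,
    min_similarity: float = 0.80,
    insert_range: tuple[int, int] = (180, 250),
) -> tuple[dict[str, HitSet], dict[str, int]]:
    """Map pairs and fragments in one pass, using pairing to break ties.

    Mates are mapped independently; when any combination of their tied hits
    forms a proper pair (same sequence, forward/reverse orientation, outer
    span within the insert range), tied hits not participating in a proper
    combination are demoted from the HitSet.
    """
    hitsets: dict[str, HitSet] = {}
    report = {"n_pairs": len(pairs), "n_proper_pairs": 0, "n_demoted_hits": 0}
    for p in pairs:
        h1 = map_read(p.r1, index, db, min_length_fraction, min_similarity)
        h2 = map_read(p.r2, index, db, min_length_fraction, min_similarity)
        if h1.hits and h2.hits:
            keep1 = set()
            keep2 = set()
            for i, a in enumerate(h1.hits):
                for j, b in enumerate(h2.hits):
                    if _is_proper(a, b, insert_range):
                        keep1.add(i)
                        keep2.add(j)
            if keep1:
                report["n_proper_pairs"] += 1
                for hs, keep in ((h1, keep1), (h2, keep2)):
                    if len(keep) < len(hs.hits):
                        report["n_demoted_hits"] += len(hs.hits) - len(keep)
                        hs.suppressed_count += len(hs.hits) - len(keep)
                        hs.hits = [a for t, a in enumerate(hs.hits) if t in keep]
        hitsets[p.r1.id] = h1
        hitsets[p.r2.id] = h2
    for f in fragments:
        hitsets[f.id] = map_read(f, index, db, min_length_fraction, min_similarity)
    return hitsets, report


# ---------------------------------------------------------------------------
# SAM import / export


def _sam_header(db: ReferenceDB) -> dict:
    sq = []
    for strain in db.strains:
        for sid in strain.sequence_ids:
            sq.append({"SN": sid, "LN": len(db.sequences[sid])})
    return {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": sq}


def write_sam(
    placements: Sequence["Placement"],
    db: ReferenceDB,
    path: str | Path,
    reads: dict[str, ReadRecord] | None = None,
) -> None:
    """Write resolved placements as SAM (1-based POS; MAPQ 0 for tied reads).

    Reads that resolved to multiple placements (topN / all-hits strategies)
    get one primary record and secondary records for the rest. Unmapped and
    tie-suppressed reads are emitted as unmapped records (the latter tagged
    ``ZS:Z:suppressed_multi``). Records are queryname-sorted, so the output
    bytes do not depend on the order reads were processed in.
    """
    from .resolve import Placement  # local import to avoid a cycle

    header = pysam.AlignmentHeader.from_dict(_sam_header(db))
    tid = {sid: t for t, sid in enumerate(header.references)}
    by_read: dict[str, list[Placement]] = {}
    for pl in placements:
        by_read.setdefault(pl.read_id, []).append(pl)
    order = sorted(by_read)

    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rid in order:
            for rank, pl in enumerate(by_read[rid]):
                seg = pysam.AlignedSegment(header)
                read = reads.get(rid) if reads else None
                qname = rid
                flag = 0
                mate = read.mate if read else 0
                if rid.endswith("/1") or rid.endswith("/2"):
                    mate = int(rid[-1])
                    qname = rid[:-2]
                if mate:
                    flag |= 0x1 | (0x40 if mate == 1 else 0x80)
                seg.query_name = qname
                if pl.status == "placed" and pl.alignment is not None:
                    a = pl.alignment
                    if a.strand == "-":
                        flag |= 0x10
                    if rank > 0:
                        flag |= 0x100
                    seg.flag = flag
                    seg.reference_id = tid[a.sequence_id]
                    seg.reference_start = a.ref_start
                    seg.mapping_quality = 0 if pl.tie_count >= 2 else 60
                    seg.cigarstring = a.cigar
                    if read is not None:
                        seq = read.seq if a.strand == "+" else revcomp(read.seq)
                        qual = read.qual if a.strand == "+" else read.qual[::-1]
                        seg.query_sequence = seq
                        seg.query_qualities = pysam.qualitystring_to_array(qual)
                    seg.set_tag("AS", a.score, "i")
                    seg.set_tag("NM", a.columns - a.matches, "i")
                    seg.set_tag("ZT", pl.tie_count, "i")
                else:
                    seg.flag = flag | 0x4
                    seg.reference_id = -1
                    seg.reference_start = -1
                    seg.mapping_quality = 0
                    if read is not None:
                        seg.query_sequence = read.seq
                        seg.query_qualities = pysam.qualitystring_to_array(read.qual)
                    if pl.status == "suppressed_multi":
                        seg.set_tag("ZS", "suppressed_multi", "Z")
                        seg.set_tag("ZT", pl.tie_count, "i")
                fh.write(seg)


def _score_from_cigar(seg: pysam.AlignedSegment) -> tuple[int, int, int, int]:
    """(score, matches, columns, query_aligned) recomputed from CIGAR + NM."""
    m_cols = i_cols = d_cols = 0
    gap_runs = 0
    for op, ln in seg.cigartuples or []:
        if op in (0, 7, 8):
            m_cols += ln
        elif op == 1:
            i_cols += ln
            gap_runs += 1
        elif op == 2:
            d_cols += ln
            gap_runs += 1
    nm = seg.get_tag("NM") if seg.has_tag("NM") else i_cols + d_cols
    mismatches = max(0, int(nm) - i_cols - d_cols)
    matches = m_cols - mismatches
    columns = m_cols + i_cols + d_cols
    score = (
        matches * MATCH
        + mismatches * MISMATCH
        - gap_runs * GAP_OPEN
        - (i_cols + d_cols - gap_runs) * GAP_EXT
    )
    return score, matches, columns, m_cols + i_cols


def read_sam(path: str | Path, db: ReferenceDB) -> dict[str, HitSet]:
    """Ingest a SAM file (ours or an external aligner's) into HitSets.

    Records are grouped per read instance (mate suffixes restored from
    flags); only the top-scoring placements are kept, scored by the AS tag
    when present and otherwise recomputed from CIGAR + NM.
    """
    known = {sid for s in db.strains for sid in s.sequence_ids}
    hitsets: dict[str, HitSet] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for lineno, seg in enumerate(fh, 1):
            rid = seg.query_name
            if seg.is_paired:
                rid += "/1" if seg.is_read1 else "/2"
            hs = hitsets.setdefault(rid, HitSet(read_id=rid))
            if seg.is_unmapped:
                continue
            if seg.reference_name not in known:
                raise ValueError(
                    f"{path}: unknown reference {seg.reference_name!r}"
                )
            if seg.has_tag("AS"):
                score = int(seg.get_tag("AS"))
                _, matches, columns, q_aln = _score_from_cigar(seg)
            else:
                score, matches, columns, q_aln = _score_from_cigar(seg)
            rl = seg.infer_read_length() or (q_aln or 1)
            aln = Alignment(
                read_id=rid,
                sequence_id=seg.reference_name,
                ref_start=seg.reference_start,
                ref_end=seg.reference_end,
                strand="-" if seg.is_reverse else "+",
                score=score,
                matches=matches,
                columns=columns,
                query_aligned=q_aln,
                read_length=rl,
                cigar=seg.cigarstring or "",
            )
            if hs.best_score is None or score > hs.best_score:
                hs.suppressed_count += len(hs.hits)
                hs.best_score = score
                hs.hits = [aln]
            elif score == hs.best_score:
                hs.hits.append(aln)
            else:
                hs.suppressed_count += 1
    return hitsets
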