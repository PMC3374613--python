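"""Seed index, read mapping under similarity/length filters, pairing, SAM I/O."""
from __future__ import annotations

import numpy as np
import pytest

from mockmap.align import (
    band_half_width,
    build_index,
    map_pairs,
    map_read,
    read_sam,
    write_sam,
)
from mockmap.mocksim import CommunitySpec, simulate_community
from mockmap.reads import ReadPair, ReadRecord, revcomp
from mockmap.refdb import ReferenceDB
from mockmap.resolve import resolve

from conftest import build_db, random_seq
from oracles import sw_best_score_both_strands


class TestBuildIndex:
    def test_position_count_small_reference(self, rng):
        db = build_db({"AA": random_seq(1000, rng)})
        idx = build_index(db, k=16)
        assert len(idx.positions) <= 1000 - 16 + 1

    def test_repetitive_seed_dropped(self):
        db = build_db({"AA": "A" * 1000})
        idx = build_index(db, k=16, max_seed_occupancy=100)
        assert len(idx.positions) == 0  # poly-A seed occupancy 985 > 100

    def test_empty_database(self):
        idx = build_index(ReferenceDB())
        assert len(idx.positions) == 0 and idx.seq_ids == []


class TestMapRead:
    def test_perfect_unique_hit(self, small_db):
        ref = small_db.sequences["AA_chr"]
        read = ReadRecord(id="q", seq=ref[5000:5100])
        idx = build_index(small_db)
        hs = map_read(read, idx, small_db)
        assert len(hs.hits) == 1
        a = hs.hits[0]
        assert a.sequence_id == "AA_chr" and a.ref_start == 5000
        assert a.identity == 1.0 and a.query_aligned_fraction == 1.0
        assert a.strand == "+" and a.score == 100

    def test_reverse_strand_hit(self, small_db):
        ref = small_db.sequences["BB_chr"]
        read = ReadRecord(id="q", seq=revcomp(ref[800:900]))
        idx = build_index(small_db)
        hs = map_read(read, idx, small_db)
        assert len(hs.hits) == 1
        a = hs.hits[0]
        assert (a.sequence_id, a.ref_start, a.strand) == ("BB_chr", 800, "-")

    def test_duplicated_segment_gives_two_tied_hits(self, rng):
        seg = random_seq(300, rng)
        chrom = random_seq(2000, rng) + seg + random_seq(2000, rng) + seg + random_seq(500, rng)
        db = build_db({"AA": chrom})
        idx = build_index(db)
        read = ReadRecord(id="q", seq=seg[100:200])
        hs = map_read(read, idx, db)
        assert len(hs.hits) == 2
        assert hs.hits[0].score == hs.hits[1].score
        assert {a.ref_start for a in hs.hits} == {2100, 4400}

    def test_too_many_substitutions_fails_similarity_filter(self, small_db, rng):
        ref = small_db.sequences["AA_chr"]
        read = list(ref[3000:3100])
        # 21 substitutions spread evenly: no 75%-length window reaches 80% id
        for p in range(2, 100, 5)[:21]:
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        idx = build_index(small_db)
        hs = map_read(
            ReadRecord(id="q", seq="".join(read)), idx, small_db,
            min_length_fraction=0.75, min_similarity=0.80,
        )
        assert hs.hits == []

    def test_read_shorter_than_seed_unmapped(self, small_db):
        idx = build_index(small_db)
        with pytest.warns(UserWarning):
            hs = map_read(ReadRecord(id="q", seq="ACGTACGT"), idx, small_db)
        assert hs.hits == []

    def test_all_reported_hits_satisfy_filters(self, small_db, rng):
        idx = build_index(small_db)
        spec = CommunitySpec(
            members=[("AA", 1.0), ("BB", 1.0)], n_pairs=100,
            substitution_rate=0.03, seed=9,
        )
        sim = simulate_community(small_db, spec)
        for p in sim.pairs[:60]:
            for r in (p.r1, p.r2):
                hs = map_read(r, idx, small_db, 0.75, 0.80)
                for a in hs.hits:
                    assert a.identity >= 0.80
                    assert a.query_aligned_fraction >= 0.75
                    assert a.score == hs.best_score

    def test_best_score_matches_full_dp_oracle(self, rng):
        """Banded seeded extension equals exhaustive full-matrix DP."""
        chrom = random_seq(20_000, rng)
        db = build_db({"AA": chrom})
        idx = build_index(db)
        for t in range(30):
            m = 100
            start = int(rng.integers(0, 20_000 - m))
            read = list(chrom[start : start + m])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, len(read)))
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            if t % 3 == 0:
                p = int(rng.integers(10, len(read) - 10))
                del read[p : p + int(rng.integers(1, 3))]
            seq = "".join(read)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            hs = map_read(
                ReadRecord(id=f"q{t}", seq=seq), idx, db,
                min_length_fraction=0.5, min_similarity=0.80,
            )
            oracle = sw_best_score_both_strands(seq, [chrom])
            assert hs.best_score == oracle


class TestMapPairs:
    def make_proper_pair(self, db, sid, start, insert, rl=100):
        ref = db.sequences[sid]
        r1 = ReadRecord(id="p0/1", seq=ref[start : start + rl], mate=1)
        r2 = ReadRecord(
            id="p0/2", seq=revcomp(ref[start + insert - rl : start + insert]), mate=2
        )
        return ReadPair(r1, r2)

    def test_unique_proper_pair_unchanged(self, small_db):
        idx = build_index(small_db)
        pair = self.make_proper_pair(small_db, "AA_chr", 4000, 200)
        hitsets, report = map_pairs([pair], [], idx, small_db)
        assert len(hitsets["p0/1"].hits) == 1
        assert len(hitsets["p0/2"].hits) == 1
        assert report["n_proper_pairs"] == 1

    def test_pairing_breaks_tie(self, rng):
        # mate A's segment occurs twice; only one copy pairs with unique B
        seg = random_seq(100, rng)
        uniq = random_seq(100, rng)
        chrom = (
            random_seq(1000, rng) + seg + random_seq(30, rng) + uniq
            + random_seq(3000, rng) + seg + random_seq(1000, rng)
        )
        db = build_db({"AA": chrom})
        idx = build_index(db)
        r1 = ReadRecord(id="p0/1", seq=seg, mate=1)
        r2 = ReadRecord(id="p0/2", seq=revcomp(uniq), mate=2)
        solo = map_read(r1, idx, db)
        assert len(solo.hits) == 2  # tied without pairing information
        hitsets, report = map_pairs([ReadPair(r1, r2)], [], idx, db)
        assert len(hitsets["p0/1"].hits) == 1
        assert hitsets["p0/1"].hits[0].ref_start == 1000
        assert report["n_demoted_hits"] == 1

    def test_fragments_match_single_read_mapping(self, small_db, rng):
        idx = build_index(small_db)
        frags = [
            ReadRecord(id=f"f{i}", seq=small_db.sequences["CC_chr"][s : s + 100])
            for i, s in enumerate(range(0, 2000, 400))
        ]
        hitsets, _ = map_pairs([], frags, idx, small_db)
        for f in frags:
            solo = map_read(f, idx, small_db)
            assert [
                (a.sequence_id, a.ref_start, a.strand) for a in hitsets[f.id].hits
            ] == [(a.sequence_id, a.ref_start, a.strand) for a in solo.hits]


class TestFilterMonotonicity:
    def test_mapped_reads_non_increasing_in_both_filters(self, small_db):
        spec = CommunitySpec(
            members=[("AA", 1.0), ("BB", 1.0), ("CC", 1.0)],
            n_pairs=150, substitution_rate=0.02, seed=13,
        )
        sim = simulate_community(small_db, spec)
        idx = build_index(small_db)
        reads = [r for p in sim.pairs for r in (p.r1, p.r2)]

        def n_mapped(lf, s):
            return sum(bool(map_read(r, idx, small_db, lf, s)) for r in reads)

        grid = {}
        for lf in (0.5, 0.75, 1.0):
            for s in (0.8, 0.9):
                grid[(lf, s)] = n_mapped(lf, s)
        for s in (0.8, 0.9):
            assert grid[(0.5, s)] >= grid[(0.75, s)] >= grid[(1.0, s)]
        for lf in (0.5, 0.75, 1.0):
            assert grid[(lf, 0.8)] >= grid[(lf, 0.9)]


class TestSamRoundTrip:
    def test_write_then_read_preserves_placements(self, small_db, tmp_path):
        spec = CommunitySpec(
            members=[("AA", 1.0), ("BB", 1.0)], n_pairs=50, seed=21,
        )
        sim = simulate_community(small_db, spec)
        idx = build_index(small_db)
        hitsets, _ = map_pairs(sim.pairs, [], idx, small_db)
        placements = resolve(hitsets, "top_random", seed=5)
        reads = {r.id: r for p in sim.pairs for r in (p.r1, p.r2)}
        sam = tmp_path / "out.sam"
        write_sam(placements, small_db, sam, reads=reads)
        back = read_sam(sam, small_db)
        placed = {p.read_id: p for p in placements if p.status == "placed"}
        assert set(back) == {p.read_id for p in placements}
        for rid, pl in placed.items():
            assert len(back[rid].hits) == 1
            b = back[rid].hits[0]
            a = pl.alignment
            assert (b.sequence_id, b.ref_start, b.ref_end, b.strand) == (
                a.sequence_id, a.ref_start, a.ref_end, a.strand,
            )
            assert b.score == a.score

    def test_unmapped_flag_yields_empty_hitset(self, small_db, tmp_path):
        sam = tmp_path / "u.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n")
            for s in small_db.strains:
                for sid in s.sequence_ids:
                    fh.write(f"@SQ\tSN:{sid}\tLN:{len(small_db.sequences[sid])}\n")
            fh.write("readX\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
        back = read_sam(sam, small_db)
        assert back["readX"].hits == []

    def test_tied_read_written_with_mapq_zero(self, rng, tmp_path):
        seg = random_seq(200, rng)
        chrom = random_seq(500, rng) + seg + random_seq(2000, rng) + seg + random_seq(500, rng)
        db = build_db({"AA": chrom})
        idx = build_index(db)
        read = ReadRecord(id="t0", seq=seg[50:150])
        hs = map_read(read, idx, db)
        assert len(hs.hits) == 2
        placements = resolve({"t0": hs}, "top_random", seed=1)
        sam = tmp_path / "t.sam"
        write_sam(placements, db, sam, reads={"t0": read})
        line = [l for l in sam.read_text().splitlines() if not l.startswith("@")][0]
        assert line.split("\t")[4] == "0"  # MAPQ 0 for a tie-resolved read

    def test_unknown_reference_is_error(self, small_db, tmp_path):
        sam = tmp_path / "bad.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:XX_chr\tLN:1000\n")
            fh.write("r0\t0\tXX_chr\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
        with pytest.raises(ValueError, match="XX_chr"):
            read_sam(sam, small_db)
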