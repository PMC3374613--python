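"""Strain-indexed reference genome database: loading, tagging, dereplication
and amendment.

Every sequence in the database carries a short strain prefix at the start of
its record ID (``<prefix>_<original id>``), so any alignment can be related
back to its parent genome and rolled up through the strain's taxonomic
lineage. Redundant genomes within a species are removed by genome-wide
k-mer containment: within each species the genomes are visited longest
chromosome first and a candidate is dropped when it shares more than a
threshold fraction of its k-mers with an already-kept representative.
Strains flagged as protected (e.g. isolates a project has committed to
tracking) are always retained and still act as representatives. Plasmids are
set aside during the similarity screen and restored for every kept strain.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

from ._kmers import canonical_kmer_set


@dataclass
class StrainRecord:
    """One genome's identity within the database."""

    prefix: str
    strain_name: str
    species: str
    genus: str
    superkingdom: str = "Bacteria"
    sequence_ids: list[str] = field(default_factory=list)
    chromosome_length: int = 0
    plasmid_ids: list[str] = field(default_factory=list)
    protected: bool = False


@dataclass
class ReferenceDB:
    """A collection of strain genomes with a sequence store.

    ``sequences`` maps every FASTA record ID (prefix-tagged) to its
    nucleotide string; each ID belongs to exactly one strain.
    """

    strains: list[StrainRecord] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def get_strain(self, prefix: str) -> StrainRecord:
        for s in self.strains:
            if s.prefix == prefix:
                return s
        raise KeyError(f"no strain with prefix {prefix!r}")

    def strain_of_sequence(self, sequence_id: str) -> StrainRecord:
        strain = self._seq_to_strain().get(sequence_id)
        if strain is None:
            raise KeyError(f"sequence {sequence_id!r} not in database")
        return strain

    def _seq_to_strain(self) -> dict[str, StrainRecord]:
        if getattr(self, "_seq_map", None) is None or len(
            self._seq_map
        ) != len(self.sequences):
            self._seq_map = {
                sid: s for s in self.strains for sid in s.sequence_ids
            }
        return self._seq_map

    def strain_length(self, prefix: str) -> int:
        """Total genome length (chromosome + plasmids) of one strain."""
        s = self.get_strain(prefix)
        return sum(len(self.sequences[sid]) for sid in s.sequence_ids)

    def chromosome_sequences(self, prefix: str) -> list[str]:
        s = self.get_strain(prefix)
        return [
            self.sequences[sid]
            for sid in s.sequence_ids
            if sid not in set(s.plasmid_ids)
        ]

    def validate(self) -> None:
        seen_prefix: set[str] = set()
        seen_seq: set[str] = set()
        for s in self.strains:
            if s.prefix in seen_prefix:
                raise ValueError(f"duplicate strain prefix {s.prefix!r}")
            seen_prefix.add(s.prefix)
            if s.chromosome_length <= 0:
                raise ValueError(
                    f"strain {s.prefix!r} has no chromosome sequence"
                )
            for sid in s.sequence_ids:
                if not sid.startswith(s.prefix):
                    raise ValueError(
                        f"sequence {sid!r} does not carry prefix {s.prefix!r}"
                    )
                if sid in seen_seq:
                    raise ValueError(f"sequence ID {sid!r} appears twice")
                seen_seq.add(sid)
                if sid not in self.sequences:
                    raise ValueError(f"sequence {sid!r} missing from store")


class RemovalRecord(NamedTuple):
    prefix: str
    kept_by: str
    similarity: float


def _is_plasmid(record_id: str, description: str = "") -> bool:
    text = (record_id + " " + description).lower()
    return "plasmid" in text


def load_database(fasta_path: str | Path, index_path: str | Path) -> ReferenceDB:
    """Load a prefix-tagged FASTA plus its strain index TSV.

    The index has columns prefix, strain_name, species, genus, superkingdom,
    protected(0/1), optionally preceded by a header line. Every FASTA record
    ID must begin with ``<prefix>_`` for exactly one indexed prefix (longest
    match wins when prefixes nest).
    """
    strains: dict[str, StrainRecord] = {}
    with open(index_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "prefix":
                continue
            if len(parts) < 5:
                raise ValueError(
                    f"{index_path}:{lineno}: expected >=5 tab-separated columns"
                )
            prefix, strain_name, species, genus, superkingdom = parts[:5]
            protected = bool(int(parts[5])) if len(parts) > 5 else False
            if prefix in strains:
                raise ValueError(f"duplicate prefix {prefix!r} in index")
            strains[prefix] = StrainRecord(
                prefix=prefix,
                strain_name=strain_name,
                species=species,
                genus=genus,
                superkingdom=superkingdom,
                protected=protected,
            )

    db = ReferenceDB(strains=list(strains.values()))
    # longest-first so nested prefixes resolve unambiguously
    ordered_prefixes = sorted(strains, key=len, reverse=True)
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        owner = None
        for p in ordered_prefixes:
            if rec.id == p or rec.id.startswith(p + "_"):
                owner = strains[p]
                break
        if owner is None:
            raise ValueError(
                f"FASTA record {rec.id!r} has no matching prefix in the index"
            )
        seq = str(rec.seq).upper()
        db.sequences[rec.id] = seq
        owner.sequence_ids.append(rec.id)
        if _is_plasmid(rec.id, rec.description):
            owner.plasmid_ids.append(rec.id)
        else:
            owner.chromosome_length += len(seq)

    db.strains = [s for s in db.strains if s.sequence_ids]
    if db.strains:
        db.validate()
    return db


def genome_similarity(
    seqs_a: Sequence[str], seqs_b: Sequence[str], k: int = 21
) -> float:
    """Genome-wide similarity as canonical k-mer containment.

    Returns |shared distinct canonical k-mers| divided by the distinct k-mer
    count of the k-mer-poorer genome, so a genome that is a subset of the
    other scores near 1 regardless of argument order.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    set_a: set[int] = set()
    for s in seqs_a:
        set_a |= canonical_kmer_set(s, k)
    set_b: set[int] = set()
    for s in seqs_b:
        set_b |= canonical_kmer_set(s, k)
    if not set_a or not set_b:
        warnings.warn("genome shorter than k; similarity defined as 0")
        return 0.0
    return len(set_a & set_b) / min(len(set_a), len(set_b))


def estimate_identity(containment: float, k: int) -> float:
    """Genome-wide identity estimated from k-mer containment.

    Under independent substitutions at per-base rate r, a k-mer survives
    with probability (1-r)^k, so containment C ~ (1-r)^k and the average
    nucleotide identity is about 1 + ln(C)/k (the Mash-distance estimator).
    This puts the dereplication threshold on the same percent-identity
    scale as genome-wide pairwise alignment. Clamped to [0, 1]; zero
    containment maps to identity 0.
    """
    if containment <= 0:
        return 0.0
    return max(0.0, min(1.0, 1.0 + math.log(containment) / k))


def dereplicate(
    db: ReferenceDB, threshold: float = 0.90, k: int = 21
) -> tuple[ReferenceDB, list[RemovalRecord]]:
    """Remove near-redundant genomes within each species.

    Genomes of a species are visited in order of decreasing chromosome
    length (prefix as tie-break) and greedily admitted; a candidate is
    removed when its estimated genome-wide identity to any already-kept
    genome of the species exceeds ``threshold`` (percent-identity scale,
    see :func:`estimate_identity`), unless it is protected. Similarity is
    computed on chromosome sequences only; plasmids of kept strains are
    carried over. The removal log records the triggering kept genome and
    the identity estimate.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    by_species: dict[tuple[str, str], list[StrainRecord]] = {}
    for s in db.strains:
        by_species.setdefault((s.genus, s.species), []).append(s)

    kept_prefixes: list[str] = []
    removed: list[RemovalRecord] = []
    kmer_cache: dict[str, set[int]] = {}

    def kmers_of(prefix: str) -> set[int]:
        if prefix not in kmer_cache:
            out: set[int] = set()
            for seq in db.chromosome_sequences(prefix):
                out |= canonical_kmer_set(seq, k)
            kmer_cache[prefix] = out
        return kmer_cache[prefix]

    for _, members in sorted(by_species.items()):
        members = sorted(members, key=lambda s: (-s.chromosome_length, s.prefix))
        kept_here: list[StrainRecord] = []
        for cand in members:
            if cand.protected:
                kept_here.append(cand)
                kept_prefixes.append(cand.prefix)
                continue
            cand_kmers = kmers_of(cand.prefix)
            hit = None
            for rep in kept_here:
                rep_kmers = kmers_of(rep.prefix)
                if not cand_kmers or not rep_kmers:
                    continue
                containment = len(cand_kmers & rep_kmers) / min(
                    len(cand_kmers), len(rep_kmers)
                )
                ident = estimate_identity(containment, k)
                if ident > threshold:
                    hit = (rep.prefix, ident)
                    break
            if hit is None:
                kept_here.append(cand)
                kept_prefixes.append(cand.prefix)
            else:
                removed.append(RemovalRecord(cand.prefix, hit[0], hit[1]))

    keep = set(kept_prefixes)
    new_strains = [s for s in db.strains if s.prefix in keep]
    new_sequences = {
        sid: db.sequences[sid] for s in new_strains for sid in s.sequence_ids
    }
    return ReferenceDB(strains=new_strains, sequences=new_sequences), removed


def amend_database(
    db: ReferenceDB,
    swaps: Iterable[tuple[Sequence[str], tuple[StrainRecord, dict[str, str]] | None]],
) -> ReferenceDB:
    """Replace strains with congeners (or simply remove them).

    Each swap is ``(remove_prefixes, add)`` where ``add`` is either None or a
    ``(StrainRecord, sequences)`` pair for the replacement strain. Strains
    not named in any swap are untouched.
    """
    existing = {s.prefix for s in db.strains}
    to_remove: set[str] = set()
    additions: list[tuple[StrainRecord, dict[str, str]]] = []
    for remove_prefixes, add in swaps:
        for p in remove_prefixes:
            if p not in existing:
                raise ValueError(f"cannot remove unknown prefix {p!r}")
            to_remove.add(p)
        if add is not None:
            additions.append(add)

    new_strains = [s for s in db.strains if s.prefix not in to_remove]
    new_sequences = {
        sid: db.sequences[sid] for s in new_strains for sid in s.sequence_ids
    }
    for strain, seqs in additions:
        new_strains.append(strain)
        for sid in strain.sequence_ids:
            if sid not in seqs:
                raise ValueError(
                    f"added strain {strain.prefix!r} missing sequence {sid!r}"
                )
            new_sequences[sid] = seqs[sid].upper()
    out = ReferenceDB(strains=new_strains, sequences=new_sequences)
    out.validate()
    return out


def write_database(
    db: ReferenceDB, fasta_path: str | Path, index_path: str | Path
) -> None:
    """Write the database back to a prefix-tagged FASTA + strain index TSV."""
    with open(fasta_path, "w") as fh:
        for s in db.strains:
            for sid in s.sequence_ids:
                fh.write(f">{sid}\n")
                seq = db.sequences[sid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    with open(index_path, "w") as fh:
        fh.write("prefix\tstrain_name\tspecies\tgenus\tsuperkingdom\tprotected\n")
        for s in db.strains:
            fh.write(
                f"{s.prefix}\t{s.strain_name}\t{s.species}\t{s.genus}\t"
                f"{s.superkingdom}\t{int(s.protected)}\n"
            )


def write_removal_log(removed: list[RemovalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("prefix\tkept_by\tsimilarity\n")
        for r in removed:
            fh.write(f"{r.prefix}\t{r.kept_by}\t{r.similarity:.6f}\n")
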