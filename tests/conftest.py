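"""Shared fixtures: in-memory synthetic reference databases and sequence helpers."""
from __future__ import annotations

import numpy as np
import pytest

from mockmap.refdb import ReferenceDB, StrainRecord

BASES = "ACGT"


def random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases i.i.d. at ``rate``, never reproducing the original."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = {ord(b): i for i, b in enumerate(BASES)}
    codes = np.array([lut[c] for c in arr], dtype=np.uint8)
    mask = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    codes[mask] = (codes[mask] + shift) % 4
    return "".join(BASES[c] for c in codes)


def build_db(
    genomes: dict[str, str] | list[tuple[str, str]],
    taxonomy: dict[str, tuple[str, str]] | None = None,
    protected: set[str] | None = None,
    plasmids: dict[str, str] | None = None,
) -> ReferenceDB:
    """Assemble a ReferenceDB from {prefix: chromosome_sequence}.

    ``taxonomy`` maps prefix -> (genus, species); defaults to one genus and
    species per strain. ``plasmids`` maps prefix -> plasmid sequence.
    """
    items = list(genomes.items()) if isinstance(genomes, dict) else genomes
    taxonomy = taxonomy or {}
    protected = protected or set()
    plasmids = plasmids or {}
    strains: list[StrainRecord] = []
    seqs: dict[str, str] = {}
    for prefix, chrom in items:
        genus, species = taxonomy.get(prefix, (f"Genus{prefix}", f"sp{prefix}"))
        sid = f"{prefix}_chr"
        sequence_ids = [sid]
        plasmid_ids = []
        seqs[sid] = chrom
        if prefix in plasmids:
            pid = f"{prefix}_plasmid1"
            sequence_ids.append(pid)
            plasmid_ids.append(pid)
            seqs[pid] = plasmids[prefix]
        strains.append(
            StrainRecord(
                prefix=prefix,
                strain_name=f"strain_{prefix}",
                species=species,
                genus=genus,
                sequence_ids=sequence_ids,
                chromosome_length=len(chrom),
                plasmid_ids=plasmid_ids,
                protected=prefix in protected,
            )
        )
    db = ReferenceDB(strains=strains, sequences=seqs)
    db.validate()
    return db


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def small_db(rng) -> ReferenceDB:
    """Three mutually dissimilar 20 kb strains in three genera."""
    return build_db({p: random_seq(20_000, rng) for p in ("AA", "BB", "CC")})
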