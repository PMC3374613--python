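"""Resolution of multi-mapping reads under alternative reporting strategies.

Short reads from conserved regions align equally well to several reference
loci (mapping quality 0). How those ties are reported decides the trade-off
between sensitivity and taxonomic resolution:

* ``top_random`` — one best hit per read; ties broken uniformly at random.
* ``unique_only`` — a read is reported only when its best placement is
  unique; tied reads are suppressed.
* ``topN`` — all tied hits are reported when there are at most N of them,
  otherwise the read is suppressed entirely.
* ``all_hits`` — every tied best hit is reported.

Random tie-breaking draws from a generator keyed on (seed, read_id), so the
outcome is independent of read processing order and reproducible.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import Alignment, HitSet

STRATEGIES = ("top_random", "unique_only", "topN", "all_hits")


@dataclass
class Placement:
    read_id: str
    alignment: Alignment | None
    status: str  # placed | unmapped | suppressed_multi
    tie_count: int = 0


def _tie_choice(seed: int, read_id: str, n: int) -> int:
    """Order-independent uniform choice among ``n`` tied hits."""
    digest = hashlib.blake2b(
        f"{seed}:{read_id}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % n


def resolve(
    hitsets: Mapping[str, HitSet] | Iterable[HitSet],
    strategy: str = "top_random",
    seed: int | None = None,
    topn: int = 5,
) -> list[Placement]:
    """Convert HitSets into final placements under one reporting strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    if strategy == "top_random" and seed is None:
        raise ValueError("top_random requires a seed (reproducibility contract)")
    if strategy == "topN" and topn < 1:
        raise ValueError("topN requires N >= 1")
    if isinstance(hitsets, Mapping):
        items = list(hitsets.values())
    else:
        items = list(hitsets)

    out: list[Placement] = []
    for hs in items:
        n = len(hs.hits)
        if n == 0:
            out.append(Placement(hs.read_id, None, "unmapped", 0))
        elif strategy == "top_random":
            pick = 0 if n == 1 else _tie_choice(seed, hs.read_id, n)
            out.append(Placement(hs.read_id, hs.hits[pick], "placed", n))
        elif strategy == "unique_only":
            if n == 1:
                out.append(Placement(hs.read_id, hs.hits[0], "placed", 1))
            else:
                out.append(Placement(hs.read_id, None, "suppressed_multi", n))
        elif strategy == "topN":
            if n > topn:
                out.append(Placement(hs.read_id, None, "suppressed_multi", n))
            else:
                out.extend(
                    Placement(hs.read_id, a, "placed", n) for a in hs.hits
                )
        else:  # all_hits
            out.extend(Placement(hs.read_id, a, "placed", n) for a in hs.hits)
    return out


def write_resolution_log(placements: Sequence[Placement], path: str | Path) -> None:
    """TSV of suppressed and unmapped reads with their tie counts."""
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\ttie_count\n")
        for pl in placements:
            if pl.status != "placed":
                fh.write(f"{pl.read_id}\t{pl.status}\t{pl.tie_count}\n")
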