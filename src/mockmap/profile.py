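"""Per-strain breadth/depth of coverage, detection calling and taxonomic
rollup into abundance tables.

Breadth is the percentage of a strain's bases (chromosome plus plasmids)
covered by at least one aligned read; depth is the mean per-base coverage
(total aligned reference bases divided by strain length, units of x). A
strain is called detected when it clears both a minimum breadth and a
minimum depth; both thresholds are inclusive. Species/genus rollups take
the unweighted arithmetic mean of member-strain breadth and depth, and
relative abundance normalises taxon depth over the detected taxa.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .refdb import ReferenceDB
from .resolve import Placement


@dataclass
class CoverageStats:
    prefix: str
    breadth: float  # percent of strain bases covered >= 1x
    depth: float  # mean per-base coverage (x)
    covered_bases: int
    assigned_reads: int
    strain_length: int
    detected: bool = False


def compute_coverage(
    placements: Sequence[Placement], db: ReferenceDB
) -> list[CoverageStats]:
    """Accumulate per-base coverage over aligned reference spans.

    Every placed alignment contributes its [ref_start, ref_end) span; depth
    counts multiplicity, breadth does not. Strains without any placement
    get explicit zero rows.
    """
    seq_len = {sid: len(seq) for sid, seq in db.sequences.items()}
    # difference arrays per sequence, materialised lazily
    diffs: dict[str, np.ndarray] = {}
    n_reads: dict[str, int] = {}
    seq_to_prefix = {
        sid: s.prefix for s in db.strains for sid in s.sequence_ids
    }
    for pl in placements:
        if pl.status != "placed" or pl.alignment is None:
            continue
        a = pl.alignment
        if a.sequence_id not in seq_len:
            raise ValueError(f"placement on unknown sequence {a.sequence_id!r}")
        d = diffs.get(a.sequence_id)
        if d is None:
            d = np.zeros(seq_len[a.sequence_id] + 1, dtype=np.int64)
            diffs[a.sequence_id] = d
        d[a.ref_start] += 1
        d[a.ref_end] -= 1
        prefix = seq_to_prefix[a.sequence_id]
        n_reads[prefix] = n_reads.get(prefix, 0) + 1

    out: list[CoverageStats] = []
    for strain in db.strains:
        total_len = sum(seq_len[sid] for sid in strain.sequence_ids)
        covered = 0
        depth_sum = 0
        for sid in strain.sequence_ids:
            d = diffs.get(sid)
            if d is None:
                continue
            cov = np.cumsum(d[:-1])
            covered += int((cov > 0).sum())
            depth_sum += int(cov.sum())
        out.append(
            CoverageStats(
                prefix=strain.prefix,
                breadth=100.0 * covered / total_len if total_len else 0.0,
                depth=depth_sum / total_len if total_len else 0.0,
                covered_bases=covered,
                assigned_reads=n_reads.get(strain.prefix, 0),
                strain_length=total_len,
            )
        )
    return out


def apply_detection(
    stats: Sequence[CoverageStats],
    min_breadth: float = 1.0,
    min_depth: float = 0.01,
) -> list[CoverageStats]:
    """Flag strains clearing both inclusive thresholds as detected."""
    if min_breadth < 0 or min_depth < 0:
        raise ValueError("detection thresholds must be >= 0")
    return [
        replace(s, detected=(s.breadth >= min_breadth and s.depth >= min_depth))
        for s in stats
    ]


def rollup(
    stats: Sequence[CoverageStats], db: ReferenceDB, level: str = "genus"
) -> pd.DataFrame:
    """Aggregate strain coverage to strain/species/genus abundance rows.

    Taxon breadth and depth are unweighted means over member strains in the
    database; a taxon is detected when any member strain is. Relative
    abundance is taxon depth over the summed depth of detected taxa.
    """
    if level not in ("strain", "species", "genus"):
        raise ValueError("level must be strain, species or genus")
    by_prefix = {s.prefix: s for s in db.strains}

    def taxon_of(prefix: str) -> str:
        s = by_prefix[prefix]
        if level == "strain":
            return s.strain_name or s.prefix
        if level == "species":
            return f"{s.genus} {s.species}".strip()
        return s.genus

    groups: dict[str, list[CoverageStats]] = {}
    for st in stats:
        groups.setdefault(taxon_of(st.prefix), []).append(st)

    rows = []
    for taxon, members in groups.items():
        breadth = float(np.mean([m.breadth for m in members]))
        depth = float(np.mean([m.depth for m in members]))
        detected = any(m.detected for m in members)
        rows.append(
            {
                "level": level,
                "taxon": taxon,
                "breadth_pct": breadth,
                "depth_x": depth,
                "covered_bases": sum(m.covered_bases for m in members),
                "assigned_reads": sum(m.assigned_reads for m in members),
                "detected": detected,
                "n_strains_in_db": len(members),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "level",
            "taxon",
            "breadth_pct",
            "depth_x",
            "covered_bases",
            "assigned_reads",
            "detected",
            "n_strains_in_db",
        ],
    )
    denom = df.loc[df["detected"], "depth_x"].sum()
    df["relative_abundance"] = 0.0
    if denom > 0:
        df.loc[df["detected"], "relative_abundance"] = (
            df.loc[df["detected"], "depth_x"] / denom
        )
    return df.sort_values("depth_x", ascending=False).reset_index(drop=True)


def write_profile(tables: Sequence[pd.DataFrame], path: str | Path) -> None:
    pd.concat(tables, ignore_index=True).to_csv(path, sep="\t", index=False)
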