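"""Truth-based evaluation: read-fate accounting, rank correlation with true
concentrations, chi-square depth comparison and amended-database log-depth
ratios.

Because every simulated read carries its source strain, each read's mapping
outcome can be classified exactly: placed on the true strain, placed on a
different strain of the same species/genus, placed on the wrong taxon,
unmapped, or suppressed as a multi-mapper. The counts conserve the read
total, so sensitivity/resolution trade-offs between reporting strategies
can be read off directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mocksim import TruthRow
from .profile import CoverageStats
from .refdb import ReferenceDB
from .resolve import Placement

FATES = ("correct_strain", "correct_at_level", "wrong_taxon", "unmapped", "suppressed_multi")
_FATE_RANK = {f: i for i, f in enumerate(FATES)}


@dataclass
class FateCounts:
    level: str
    correct_strain: int = 0
    correct_at_level: int = 0
    wrong_taxon: int = 0
    unmapped: int = 0
    suppressed_multi: int = 0
    ambiguous_multi: int = 0  # reads with >1 emitted placement (informational)

    @property
    def total(self) -> int:
        return (
            self.correct_strain
            + self.correct_at_level
            + self.wrong_taxon
            + self.unmapped
            + self.suppressed_multi
        )

    def fractions(self) -> dict[str, float]:
        t = self.total or 1
        return {f: getattr(self, f) / t for f in FATES}


def classify_fates(
    placements: Sequence[Placement],
    truth: Mapping[str, TruthRow],
    db: ReferenceDB,
    level: str = "genus",
) -> FateCounts:
    """Assign each truth-labelled read exactly one mapping fate.

    ``level`` controls what counts as "right neighborhood, wrong strain":
    at species (genus) level a placement on another strain of the same
    species (genus) is ``correct_at_level``; at strain level only the exact
    strain is right. Reads with several emitted placements (topN/all-hits)
    take their best fate and are counted in ``ambiguous_multi``.
    Reads present in the truth table but absent from ``placements`` (e.g.
    removed during screening) count as unmapped.
    """
    if level not in ("strain", "species", "genus"):
        raise ValueError("level must be strain, species or genus")
    by_prefix = {s.prefix: s for s in db.strains}
    seq_to_prefix = {sid: s.prefix for s in db.strains for sid in s.sequence_ids}

    def placed_fate(true_prefix: str, placed_prefix: str) -> str:
        if placed_prefix == true_prefix:
            return "correct_strain"
        ts = by_prefix.get(true_prefix)
        ps = by_prefix.get(placed_prefix)
        if ts is None or ps is None:
            return "wrong_taxon"
        if level == "genus" and ts.genus == ps.genus:
            return "correct_at_level"
        if level == "species" and (ts.genus, ts.species) == (ps.genus, ps.species):
            return "correct_at_level"
        return "wrong_taxon"

    grouped: dict[str, list[Placement]] = {}
    for pl in placements:
        if pl.read_id not in truth:
            if pl.status == "placed":
                raise ValueError(f"placed read {pl.read_id!r} missing from truth")
            continue
        grouped.setdefault(pl.read_id, []).append(pl)

    fc = FateCounts(level=level)
    for rid, trow in truth.items():
        pls = grouped.get(rid)
        if not pls:
            fc.unmapped += 1
            continue
        statuses = {p.status for p in pls}
        if statuses == {"unmapped"}:
            fc.unmapped += 1
            continue
        if statuses == {"suppressed_multi"}:
            fc.suppressed_multi += 1
            continue
        placed = [p for p in pls if p.status == "placed" and p.alignment]
        fates = [
            placed_fate(trow.prefix, seq_to_prefix.get(p.alignment.sequence_id, ""))
            for p in placed
        ]
        best = min(fates, key=lambda f: _FATE_RANK[f])
        setattr(fc, best, getattr(fc, best) + 1)
        if len(placed) > 1:
            fc.ambiguous_multi += 1
    return fc


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected (average-rank) Spearman rank correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def chisq_depth_compare(
    depths_a: Sequence[float], depths_b: Sequence[float]
) -> tuple[float, float]:
    """Goodness-of-fit comparison of two per-strain depth profiles.

    Vector b is rescaled to a's total (expected e_i = b_i * sum(a)/sum(b));
    the statistic X^2 = sum (a_i - e_i)^2 / e_i is referred to the
    chi-square upper tail with n-1 degrees of freedom. Returns (X^2, p).
    A p-value >= 0.05 reads as "similar profiles".
    """
    a = np.asarray(depths_a, dtype=float)
    b = np.asarray(depths_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.any(b <= 0):
        raise ValueError(
            "zero expected depth; drop undetected strains before comparing"
        )
    e = b * (a.sum() / b.sum())
    x2 = float(((a - e) ** 2 / e).sum())
    p = float(sps.chi2.sf(x2, df=len(a) - 1))
    return x2, p


def depth_log_ratio(
    profile_ref: pd.DataFrame,
    profile_amended: pd.DataFrame,
    level: str = "genus",
) -> pd.DataFrame:
    """Paired log10 depths per taxon between a reference and an amended run.

    Taxa with zero depth (or absent from one profile) get a missing value on
    that side rather than -inf; taxa with equal depths land on the diagonal.
    """
    def series(df: pd.DataFrame) -> pd.Series:
        sub = df[df["level"] == level] if "level" in df.columns else df
        s = sub.set_index("taxon")["depth_x"]
        return s.where(s > 0).apply(np.log10)

    ref = series(profile_ref)
    amd = series(profile_amended)
    taxa = sorted(set(ref.index) | set(amd.index))
    return pd.DataFrame(
        {
            "taxon": taxa,
            "log10_depth_ref": [ref.get(t, np.nan) for t in taxa],
            "log10_depth_amended": [amd.get(t, np.nan) for t in taxa],
        }
    )


def fate_report(counts: Sequence[FateCounts]) -> pd.DataFrame:
    rows = []
    for fc in counts:
        row = {"level": fc.level, "total": fc.total, "ambiguous_multi": fc.ambiguous_multi}
        row.update({f: getattr(fc, f) for f in FATES})
        row.update({f + "_frac": v for f, v in fc.fractions().items()})
        rows.append(row)
    return pd.DataFrame(rows)
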