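"""Read containers and plain-text FASTQ I/O.

FASTQ writing is byte-deterministic (no wrapping, Sanger/Phred+33 qualities)
because downstream reproducibility contracts compare output files literally.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A single sequenced read (one mate of a pair, or a fragment)."""

    id: str
    seq: str
    qual: str = ""
    mate: int = 0  # 0 = fragment, 1/2 = mate number

    def __post_init__(self) -> None:
        if not self.qual:
            self.qual = "I" * len(self.seq)
        if len(self.qual) != len(self.seq):
            raise ValueError(f"quality/sequence length mismatch for {self.id}")


@dataclass
class ReadPair:
    r1: ReadRecord
    r2: ReadRecord


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            rid = header.strip()[1:].split()[0]
            mate = 0
            if rid.endswith("/1"):
                mate = 1
            elif rid.endswith("/2"):
                mate = 2
            yield ReadRecord(id=rid, seq=seq, qual=qual, mate=mate)


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    r1s = list(read_fastq(path1))
    r2s = list(read_fastq(path2))
    if len(r1s) != len(r2s):
        raise ValueError(
            f"mate files have unequal read counts: {len(r1s)} vs {len(r2s)}"
        )
    return [ReadPair(a, b) for a, b in zip(r1s, r2s)]
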