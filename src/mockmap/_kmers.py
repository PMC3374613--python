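"""2-bit k-mer encoding shared by the reference-database and alignment modules.

Bases are encoded A=0, C=1, G=2, T=3; any other symbol (N, IUPAC codes) is 4
and poisons every k-mer window it touches.
"""
from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGTN"), dtype="<U1")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 array (A=0,C=1,G=2,T=3,other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[np.minimum(codes, 4)])


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of an encoded sequence.

    Returns (kmers, valid): ``kmers[i]`` packs positions ``i..i+k-1`` big-endian
    into a uint64; ``valid[i]`` is False when the window contains a non-ACGT
    base. Requires k <= 31. Length is ``len(codes) - k + 1`` (empty if shorter).
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 64-bit packing")
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    kmers = (windows.astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)
    valid = ~np.lib.stride_tricks.sliding_window_view(codes == 4, k).any(axis=1)
    return kmers, valid


def revcomp_codes(kmers: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mer codes (vectorised)."""
    out = np.zeros_like(kmers)
    tmp = kmers.copy()
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        out = (out << two) | (three - (tmp & three))
        tmp = tmp >> two
    return out


def canonical_kmer_set(seq: str, k: int) -> set[int]:
    """Distinct canonical (strand-min) k-mers of a sequence, as ints."""
    codes = encode(seq)
    kmers, valid = kmer_codes(codes, k)
    kmers = kmers[valid]
    if kmers.size == 0:
        return set()
    rc = revcomp_codes(kmers, k)
    canon = np.minimum(kmers, rc)
    return set(int(x) for x in np.unique(canon))
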