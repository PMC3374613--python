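"""Numba kernel for local alignment of a read against a reference window.

Scoring: match +1, mismatch -2, gap -3 for the first gap column and -1 for
each further column of the same gap. Alignment is local on both sequences
(unaligned read ends become soft clips), which is what the length-fraction
filter measures. Bases encoded >= 4 (N) never match.
"""
from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP_OPEN = 3  # cost of the first column of a gap
GAP_EXT = 1  # cost of each subsequent column

NEG = -(10**8)


@njit(cache=True)
def collect_diagonals(
    oriented: np.ndarray,
    k: int,
    uniq: np.ndarray,
    bounds: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Sorted unique seed diagonals (ref_pos - read_pos) for one orientation.

    Rolls a 2-bit k-mer over the read and binary-searches the sorted index
    codes; windows touching a non-ACGT base are skipped.
    """
    m = len(oriented)
    n_uniq = len(uniq)
    if m < k or n_uniq == 0:
        return np.empty(0, dtype=np.int64)
    mask = (np.uint64(1) << np.uint64(2 * k)) - np.uint64(1)
    out = np.empty(256, dtype=np.int64)
    n_out = 0
    code = np.uint64(0)
    valid_run = 0
    for i in range(m):
        b = oriented[i]
        if b >= 4:
            valid_run = 0
            code = np.uint64(0)
            continue
        code = ((code << np.uint64(2)) | np.uint64(b)) & mask
        valid_run += 1
        if valid_run < k:
            continue
        qpos = i - k + 1
        lo = np.searchsorted(uniq, code)
        if lo < n_uniq and uniq[lo] == code:
            for t in range(bounds[lo], bounds[lo + 1]):
                if n_out == len(out):
                    grown = np.empty(2 * len(out), dtype=np.int64)
                    grown[:n_out] = out[:n_out]
                    out = grown
                out[n_out] = positions[t] - qpos
                n_out += 1
    if n_out == 0:
        return np.empty(0, dtype=np.int64)
    res = np.sort(out[:n_out])
    # dedupe in place
    w = 1
    for t in range(1, n_out):
        if res[t] != res[w - 1]:
            res[w] = res[t]
            w += 1
    return res[:w]


@njit(cache=True)
def align_window(read: np.ndarray, ref: np.ndarray):
    """Best local alignment of ``read`` vs ``ref`` (both uint8-encoded).

    Returns (score, qs, qe, rs, re, matches, columns, ops, lens, n_ops)
    with 0-based half-open coordinates; ops are 0=M(match/mismatch),
    1=I(read base vs gap), 2=D(gap vs reference base).
    """
    m = len(read)
    w = len(ref)
    H = np.zeros((m + 1, w + 1), dtype=np.int32)
    E = np.full((m + 1, w + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, w + 1), NEG, dtype=np.int32)
    ptrH = np.zeros((m + 1, w + 1), dtype=np.uint8)  # 0 stop,1 diag,2 E,3 F
    ptrE = np.zeros((m + 1, w + 1), dtype=np.uint8)  # 0 open,1 extend
    ptrF = np.zeros((m + 1, w + 1), dtype=np.uint8)

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        rb = read[i - 1]
        for j in range(1, w + 1):
            e_open = H[i, j - 1] - GAP_OPEN
            e_ext = E[i, j - 1] - GAP_EXT
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - GAP_OPEN
            f_ext = F[i - 1, j] - GAP_EXT
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            if rb < 4 and rb == ref[j - 1]:
                s = MATCH
            else:
                s = MISMATCH
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    ops = np.empty(2 * (m + w) + 4, dtype=np.int32)
    lens = np.empty(2 * (m + w) + 4, dtype=np.int32)
    n_ops = 0
    matches = 0
    columns = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 1 in E, 2 in F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                if read[i - 1] < 4 and read[i - 1] == ref[j - 1]:
                    matches += 1
                columns += 1
                if n_ops > 0 and ops[n_ops - 1] == 0:
                    lens[n_ops - 1] += 1
                else:
                    ops[n_ops] = 0
                    lens[n_ops] = 1
                    n_ops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap vs reference base (D)
            columns += 1
            if n_ops > 0 and ops[n_ops - 1] == 2:
                lens[n_ops - 1] += 1
            else:
                ops[n_ops] = 2
                lens[n_ops] = 1
                n_ops += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:  # read base vs gap (I)
            columns += 1
            if n_ops > 0 and ops[n_ops - 1] == 1:
                lens[n_ops - 1] += 1
            else:
                ops[n_ops] = 1
                lens[n_ops] = 1
                n_ops += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1

    # ops were collected back-to-front; reverse in place
    for t in range(n_ops // 2):
        ops[t], ops[n_ops - 1 - t] = ops[n_ops - 1 - t], ops[t]
        lens[t], lens[n_ops - 1 - t] = lens[n_ops - 1 - t], lens[t]

    return best, i, bi, j, bj, matches, columns, ops, lens, n_ops
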