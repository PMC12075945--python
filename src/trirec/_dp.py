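"""Numba kernels for affine-gap dynamic programming.

Sequences are encoded as uint8 (A=0, C=1, G=2, T=3, N=4).  A gap of length k
costs gap_open + (k-1) * gap_extend.  Tie order at every H cell is
diagonal > up > left; inside the gap states a tie between opening (from H)
and extending resolves toward opening, so gaps close as early as possible.
Both choices make tracebacks bit-reproducible across platforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(2 ** 40))

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _ENCODE[ord(_c)] = _i


def encode(residues: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return arr


@njit(cache=True)
def _sub_score(ca, cb, match, mismatch, nscore):
    if ca == 4 or cb == 4:
        return nscore
    if ca == cb:
        return match
    return mismatch


@njit(cache=True)
def global_fill(a, b, match, mismatch, nscore, go, ge):
    """Three-state Gotoh fill; returns (score, PH, PE, PF) pointer matrices.

    PH: 0 = diagonal, 1 = up (enter E), 2 = left (enter F).
    PE/PF: 0 = gap opened from H, 1 = gap extended.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.empty((n + 1, m + 1), np.int64)
    E = np.empty((n + 1, m + 1), np.int64)
    F = np.empty((n + 1, m + 1), np.int64)
    PH = np.zeros((n + 1, m + 1), np.uint8)
    PE = np.zeros((n + 1, m + 1), np.uint8)
    PF = np.zeros((n + 1, m + 1), np.uint8)
    H[0, 0] = 0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for i in range(1, n + 1):
        E[i, 0] = -(go + (i - 1) * ge)
        H[i, 0] = E[i, 0]
        F[i, 0] = NEG
        PH[i, 0] = 1
        PE[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        F[0, j] = -(go + (j - 1) * ge)
        H[0, j] = F[0, j]
        E[0, j] = NEG
        PH[0, j] = 2
        PF[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            d = H[i - 1, j - 1] + _sub_score(a[i - 1], b[j - 1], match, mismatch, nscore)
            if d >= E[i, j] and d >= F[i, j]:
                H[i, j] = d
                PH[i, j] = 0
            elif E[i, j] >= F[i, j]:
                H[i, j] = E[i, j]
                PH[i, j] = 1
            else:
                H[i, j] = F[i, j]
                PH[i, j] = 2
    return H[n, m], PH, PE, PF


@njit(cache=True)
def local_fill(a, b, match, mismatch, nscore, go, ge, mask):
    """Smith-Waterman fill with a cell mask for Waterman-Eggert rescans.

    Masked cells are excluded from every path (H forced to 0, gap states to
    NEG).  Returns (best, bi, bj, H, PH, PE, PF) where PH: 0 = path start,
    1 = diagonal, 2 = up, 3 = left; best cell ties resolve to the smallest
    (i, j).
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    PH = np.zeros((n + 1, m + 1), np.uint8)
    PE = np.zeros((n + 1, m + 1), np.uint8)
    PF = np.zeros((n + 1, m + 1), np.uint8)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if mask[i, j]:
                H[i, j] = 0
                E[i, j] = NEG
                F[i, j] = NEG
                PH[i, j] = 0
                continue
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            d = H[i - 1, j - 1] + _sub_score(a[i - 1], b[j - 1], match, mismatch, nscore)
            h = np.int64(0)
            p = np.uint8(0)
            if d >= E[i, j] and d >= F[i, j] and d > 0:
                h = d
                p = np.uint8(1)
            elif E[i, j] >= F[i, j] and E[i, j] > 0:
                h = E[i, j]
                p = np.uint8(2)
            elif F[i, j] > 0:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, PH, PE, PF
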