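"""Banded global alignment kernel (Gotoh affine gaps), numba-compiled.

Band is expressed as a half-width ``w`` on the diagonal offset
``k = j - i + w`` so cell (i, j) is stored at column ``j - i + w`` of a
dense (n+1, 2w+1) array.  The band must contain the corner diagonal,
i.e. ``w >= |len(b) - len(a)|``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.float64(-1e18)

# traceback codes: which matrix the move came from
FROM_M, FROM_X, FROM_Y, FROM_NONE = 0, 1, 2, 3


@njit(cache=True)
def banded_affine(
    a: np.ndarray,
    b: np.ndarray,
    w: int,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
):
    """Fill banded Gotoh matrices; return (score, ptrM, ptrX, ptrY, endmat).

    Gap of length L costs ``gap_open + L * gap_extend``.  X = gap in b
    (consumes a), Y = gap in a (consumes b).
    """
    n = a.shape[0]
    m = b.shape[0]
    width = 2 * w + 1
    M = np.full((n + 1, width), NEG)
    X = np.full((n + 1, width), NEG)
    Y = np.full((n + 1, width), NEG)
    ptrM = np.full((n + 1, width), FROM_NONE, dtype=np.uint8)
    ptrX = np.full((n + 1, width), FROM_NONE, dtype=np.uint8)
    ptrY = np.full((n + 1, width), FROM_NONE, dtype=np.uint8)

    first_gap = gap_open + gap_extend

    M[0, w] = 0.0
    for j in range(1, min(m, w) + 1):
        Y[0, j + w] = gap_open + gap_extend * j
        ptrY[0, j + w] = FROM_Y if j > 1 else FROM_M

    for i in range(1, n + 1):
        klo = max(0, w - i)                 # j >= 0
        khi = min(width - 1, m - i + w)     # j <= m
        for k in range(klo, khi + 1):
            j = k - w + i
            if j == 0:
                X[i, k] = gap_open + gap_extend * i
                ptrX[i, k] = FROM_X if i > 1 else FROM_M
                continue
            # M: diagonal from (i-1, j-1) -> same k
            bestp = M[i - 1, k]
            code = FROM_M
            if X[i - 1, k] > bestp:
                bestp = X[i - 1, k]
                code = FROM_X
            if Y[i - 1, k] > bestp:
                bestp = Y[i - 1, k]
                code = FROM_Y
            if bestp > NEG / 2:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i, k] = bestp + s
                ptrM[i, k] = code
            # X: from (i-1, j) -> k+1
            if k + 1 < width:
                open_x = M[i - 1, k + 1] + first_gap
                ext_x = X[i - 1, k + 1] + gap_extend
                swap_x = Y[i - 1, k + 1] + first_gap
                bx = open_x
                cx = FROM_M
                if ext_x > bx:
                    bx = ext_x
                    cx = FROM_X
                if swap_x > bx:
                    bx = swap_x
                    cx = FROM_Y
                if bx > NEG / 2:
                    X[i, k] = bx
                    ptrX[i, k] = cx
            # Y: from (i, j-1) -> k-1
            if k - 1 >= 0:
                open_y = M[i, k - 1] + first_gap
                ext_y = Y[i, k - 1] + gap_extend
                swap_y = X[i, k - 1] + first_gap
                by = open_y
                cy = FROM_M
                if ext_y > by:
                    by = ext_y
                    cy = FROM_Y
                if swap_y > by:
                    by = swap_y
                    cy = FROM_X
                if by > NEG / 2:
                    Y[i, k] = by
                    ptrY[i, k] = cy

    kend = m - n + w
    score = M[n, kend]
    endmat = FROM_M
    if X[n, kend] > score:
        score = X[n, kend]
        endmat = FROM_X
    if Y[n, kend] > score:
        score = Y[n, kend]
        endmat = FROM_Y
    return score, ptrM, ptrX, ptrY, endmat


def traceback(a: str, b: str, w: int, ptrM, ptrX, ptrY, endmat) -> tuple[str, str]:
    """Recover one optimal alignment from the pointer matrices."""
    i, j = len(a), len(b)
    mat = endmat
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        k = j - i + w
        if mat == FROM_M:
            prev = ptrM[i, k]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif mat == FROM_X:
            prev = ptrX[i, k]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = ptrY[i, k]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        mat = int(prev)
    return "".join(reversed(out_a)), "".join(reversed(out_b))
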