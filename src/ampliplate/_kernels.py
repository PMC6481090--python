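"""Numba-compiled inner loops for overlap search and alignment.

Sequences are passed as uint8 arrays of ASCII codes.  Both kernels are
exact: the overlap scan uses integer cross-multiplication to compare
mismatch ratios without floating-point ties, and the aligner is a full
Gotoh dynamic program with recorded tracebacks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9))

# traceback state codes
ST_DIAG = 0  # match/mismatch
ST_DEL = 1  # gap in query (consumes reference)
ST_INS = 2  # gap in reference (consumes query)
ST_FREE = 3  # free leading reference skip / origin


@njit(cache=True)
def best_overlap(a: np.ndarray, b: np.ndarray, min_overlap: int) -> tuple[int, int]:
    """Best suffix(a)/prefix(b) overlap of length >= min_overlap.

    Returns (overlap_length, mismatches) minimising the mismatch ratio;
    ties are broken toward the longer overlap.  (-1, 0) if no overlap of
    the minimum length exists.
    """
    la, lb = a.shape[0], b.shape[0]
    max_l = min(la, lb)
    best_len = -1
    best_mm = 0
    for length in range(min_overlap, max_l + 1):
        off = la - length
        mm = 0
        for i in range(length):
            if a[off + i] != b[i]:
                mm += 1
        # mm/length <= best_mm/best_len, exact integer comparison;
        # equality falls through to the longer (current) overlap
        if best_len < 0 or mm * best_len <= best_mm * length:
            best_len = length
            best_mm = mm
    return best_len, best_mm


@njit(cache=True)
def semiglobal_dp(
    ref: np.ndarray,
    qry: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
):
    """Affine-gap alignment of a full query against a reference window.

    Reference overhangs at either end are free (the fragment may cover
    only part of the amplicon); every query base must be aligned.  A gap
    of length k costs gap_open + (k - 1) * gap_extend (both negative).

    Returns (score, end_ref_index, H_state, del_open, ins_open) where the
    last three are traceback matrices: H_state[i, j] records which state
    realised the best score at (ref i, query j) with the deterministic
    preference diagonal > deletion > insertion, and del_open/ins_open
    record whether the gap state opened (1) or extended (0) there.
    """
    n = ref.shape[0]
    m = qry.shape[0]
    H = np.empty((n + 1, m + 1), np.int32)
    E = np.empty((n + 1, m + 1), np.int32)  # gap in reference (insertion)
    F = np.empty((n + 1, m + 1), np.int32)  # gap in query (deletion)
    state = np.empty((n + 1, m + 1), np.uint8)
    del_open = np.zeros((n + 1, m + 1), np.uint8)
    ins_open = np.zeros((n + 1, m + 1), np.uint8)

    H[0, 0] = 0
    E[0, 0] = NEG_INF
    F[0, 0] = NEG_INF
    state[0, 0] = ST_FREE
    for i in range(1, n + 1):
        H[i, 0] = 0  # free leading reference skip
        E[i, 0] = NEG_INF
        F[i, 0] = NEG_INF
        state[i, 0] = ST_FREE
    for j in range(1, m + 1):
        if j == 1:
            E[0, j] = gap_open
        else:
            E[0, j] = E[0, j - 1] + gap_extend
        ins_open[0, j] = 1 if j == 1 else 0
        H[0, j] = E[0, j]
        F[0, j] = NEG_INF
        state[0, j] = ST_INS

    for i in range(1, n + 1):
        ri = ref[i - 1]
        for j in range(1, m + 1):
            diag = H[i - 1, j - 1] + (match if ri == qry[j - 1] else mismatch)

            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                del_open[i, j] = 1
            else:
                F[i, j] = f_ext

            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ins_open[i, j] = 1
            else:
                E[i, j] = e_ext

            best = diag
            st = ST_DIAG
            if F[i, j] > best:
                best = F[i, j]
                st = ST_DEL
            if E[i, j] > best:
                best = E[i, j]
                st = ST_INS
            H[i, j] = best
            state[i, j] = st

    # free trailing reference skip: best score over the last query column,
    # leftmost end point on ties
    best_i = 0
    best_score = H[0, m]
    for i in range(1, n + 1):
        if H[i, m] > best_score:
            best_score = H[i, m]
            best_i = i
    return best_score, best_i, state, del_open, ins_open
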