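"""Independent brute-force oracles used to cross-check the fast kernels.

Everything here is written from the problem definition, not from the
implementation: a memoised recursion over alignment states for scoring,
a direct offset scan for overlaps, and placement enumeration for indel
normalisation.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache


def oracle_semiglobal_score(ref, qry, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Exhaustive affine-gap score: full query, free reference overhangs.

    A gap of length k costs gap_open + (k-1) * gap_extend.  States track
    whether the previous column was a same-type gap.
    """
    n, m = len(ref), len(qry)

    @lru_cache(maxsize=None)
    def best(i, j, state):  # state: 0 none/diag, 1 mid-insertion, 2 mid-deletion
        if j == m:
            return 0  # trailing reference skip is free
        options = []
        if i < n:
            options.append(
                best(i + 1, j + 1, 0) + (match if ref[i] == qry[j] else mismatch)
            )
            options.append(best(i + 1, j, 2) + (gap_extend if state == 2 else gap_open))
        options.append(best(i, j + 1, 1) + (gap_extend if state == 1 else gap_open))
        return max(options)

    result = max(best(i, 0, 0) for i in range(n + 1))
    best.cache_clear()
    return result


def oracle_best_overlap(seq1, seq2_revcomp, min_overlap, max_mismatch_ratio):
    """Scan every candidate overlap length; exact rational ratio compare."""
    best = None  # (ratio, -length, mismatches)
    for length in range(min_overlap, min(len(seq1), len(seq2_revcomp)) + 1):
        tail = seq1[len(seq1) - length :]
        head = seq2_revcomp[:length]
        mm = sum(a != b for a, b in zip(tail, head))
        key = (Fraction(mm, length), -length)
        if best is None or key < best[0]:
            best = (key, length, mm)
    if best is None:
        return None
    _, length, mm = best
    if Fraction(mm, length) > Fraction(max_mismatch_ratio).limit_denominator(10**6):
        return None
    return length, mm


def oracle_leftmost_deletion(reference, pos, size):
    """Leftmost placement of a size-bp deletion equivalent to deleting
    reference[pos:pos+size], found by enumerating every placement."""
    target = reference[:pos] + reference[pos + size :]
    placements = [
        p
        for p in range(len(reference) - size + 1)
        if reference[:p] + reference[p + size :] == target
    ]
    return min(placements)


def oracle_leftmost_insertion(reference, pos, insert):
    """Leftmost equivalent placement (and rotated sequence) of an insertion."""
    target = reference[:pos] + insert + reference[pos:]
    best = None
    for p in range(len(reference) + 1):
        ins = target[p : p + len(insert)]
        if reference[:p] + ins + reference[p:] == target:
            if best is None or p < best[0]:
                best = (p, ins)
    return best
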