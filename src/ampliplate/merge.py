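"""Reconstruction of amplicon fragments from overlapping read pairs.

A 300-400 bp amplicon sequenced as 2 x 250 bp produces mates whose 3'
ends read the same molecule from opposite strands.  The merger scans
every candidate overlap length between the forward mate and the
reverse-complemented reverse mate, picks the one with the smallest
substitution mismatch ratio (ties go to the longer overlap), and builds
a consensus in which the base with the higher Phred quality wins.

Only substitutions are considered inside the overlap: both mates read
one physical molecule, so true indels between them cannot occur; indels
relative to the reference are resolved later at alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import best_overlap
from .demux import ReadPair

__all__ = [
    "MergedFragment",
    "MergeFailure",
    "find_best_overlap",
    "merge_pair",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATIO = 0.25


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class MergedFragment:
    sequence: str
    quality: str
    overlap_length: int
    overlap_mismatches: int
    source_pair_id: str


@dataclass(frozen=True)
class MergeFailure:
    source_pair_id: str
    reason: str  # "no_overlap" | "empty_mate"


def find_best_overlap(
    seq1: str,
    seq2_revcomp: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> tuple[int, int] | None:
    """Best overlap between the 3' end of seq1 and the 5' end of seq2_revcomp.

    Among all overlap lengths >= min_overlap returns (length, mismatches)
    with the minimal mismatch ratio, preferring longer overlaps on ties;
    None when no candidate meets the ratio ceiling.
    """
    if not seq1 or not seq2_revcomp:
        raise ValueError("empty sequence")
    length, mm = best_overlap(_as_bytes(seq1), _as_bytes(seq2_revcomp), min_overlap)
    if length < 0 or mm > max_mismatch_ratio * length:
        return None
    return int(length), int(mm)


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> MergedFragment | MergeFailure:
    """Merge a trimmed read pair into one amplicon fragment.

    Within the overlap the consensus takes the base with the higher Phred
    quality (tie -> mate 1's base) and the higher of the two qualities.
    The merged length always equals len(mate1) + len(mate2) - overlap.
    """
    if not pair.seq1 or not pair.seq2:
        return MergeFailure(pair.id, "empty_mate")
    s2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    found = find_best_overlap(pair.seq1, s2, min_overlap, max_mismatch_ratio)
    if found is None:
        return MergeFailure(pair.id, "no_overlap")
    length, mm = found

    l1 = len(pair.seq1)
    head_s, head_q = pair.seq1[: l1 - length], pair.qual1[: l1 - length]
    tail_s, tail_q = s2[length:], q2[length:]
    mid_s = []
    mid_q = []
    for k in range(length):
        b1, b2 = pair.seq1[l1 - length + k], s2[k]
        c1, c2 = pair.qual1[l1 - length + k], q2[k]
        if b1 == b2:
            mid_s.append(b1)
        else:
            mid_s.append(b2 if c2 > c1 else b1)
        mid_q.append(max(c1, c2))
    sequence = head_s + "".join(mid_s) + tail_s
    quality = head_q + "".join(mid_q) + tail_q
    assert len(sequence) == l1 + len(pair.seq2) - length
    return MergedFragment(
        sequence=sequence,
        quality=quality,
        overlap_length=length,
        overlap_mismatches=mm,
        source_pair_id=pair.id,
    )
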