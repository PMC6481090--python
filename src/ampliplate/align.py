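"""Semi-global alignment of amplicon fragments and allele classification.

Merged fragments are aligned to the reference amplicon with an
affine-gap dynamic program in which reference overhangs are free (a
truncated fragment aligns to the interior of the amplicon) while every
query base is aligned.  Default scoring (match +1, mismatch -2, gap open
-5, gap extend -1, a k-gap costing open + (k-1) * extend) makes a single
1 bp indel score better than two substitutions — the right prior for
Cas9 repair outcomes, where short indels at the cut site dominate.

Variants are reported left-aligned against the reference, and each
allele is classified relative to the programmed edit:

========================  =====================================================
class                     rule
========================  =====================================================
WT                        no variants
HDR                       variants exactly equal the donor substitutions
NHEJ_indel                indel present, donor changes not (all) present
substitution_only         substitutions only, not matching the donor
complex                   all donor substitutions present plus anything else
========================  =====================================================

An allele carrying the donor base *and* an indel is complex, never HDR —
the conservative call for clone selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from ._kernels import ST_DEL, ST_DIAG, ST_FREE, semiglobal_dp
from .merge import revcomp

__all__ = [
    "Scoring",
    "TargetLocus",
    "AlignmentResult",
    "Variant",
    "AlleleClass",
    "DesignNote",
    "align_semiglobal",
    "align_fragment",
    "extract_variants",
    "left_align",
    "apply_variants",
    "donor_haplotype",
    "classify_allele",
    "validate_amplicon_design",
]


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class TargetLocus:
    """Reference amplicon with genomic coordinates and regions of interest.

    ``regions_of_interest`` and ``donor_diffs`` use 0-based amplicon
    coordinates; intervals are half-open.  ``donor_diffs`` lists the
    substitutions an HDR donor template would introduce, as
    (position, reference base, donor base).
    """

    name: str
    chrom: str
    start: int
    end: int
    reference_amplicon: str
    regions_of_interest: tuple[tuple[str, int, int], ...] = ()
    donor_diffs: tuple[tuple[int, str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.reference_amplicon):
            raise ValueError(
                f"locus {self.name}: interval length {self.end - self.start} != "
                f"amplicon length {len(self.reference_amplicon)}"
            )
        n = len(self.reference_amplicon)
        for label, s, e in self.regions_of_interest:
            if not (0 <= s < e <= n):
                raise ValueError(f"region {label!r} [{s},{e}) outside amplicon [0,{n})")
        if self.donor_diffs:
            for pos, ref, alt in self.donor_diffs:
                if not 0 <= pos < n:
                    raise ValueError(f"donor substitution at {pos} outside amplicon")
                if self.reference_amplicon[pos] != ref:
                    raise ValueError(
                        f"donor substitution {pos}:{ref}>{alt} does not match "
                        f"reference base {self.reference_amplicon[pos]!r}"
                    )


class AlleleClass(str, Enum):
    WT = "WT"
    HDR = "HDR"
    NHEJ_INDEL = "NHEJ_indel"
    SUBSTITUTION_ONLY = "substitution_only"
    COMPLEX = "complex"


@dataclass(frozen=True)
class AlignmentResult:
    """Banded-free alignment of a query to the reference amplicon.

    ``operations`` is a run-length list of (op, length) with op one of
    "match", "mismatch", "insertion", "deletion" covering the aligned
    region; ``ref_start``/``ref_end`` delimit the reference span covered
    (overhangs outside it are unaligned, not deletions).
    """

    operations: tuple[tuple[str, int], ...]
    score: int
    query: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        qspan = sum(n for op, n in self.operations if op != "deletion")
        rspan = sum(n for op, n in self.operations if op != "insertion")
        if qspan != len(self.query) or rspan != self.ref_end - self.ref_start:
            raise ValueError("operation lengths inconsistent with query/reference spans")


@dataclass(frozen=True)
class Variant:
    """A left-aligned difference from the reference amplicon.

    Insertions have an empty ``ref_allele`` (bases inserted before
    ``amplicon_position``), deletions an empty ``alt_allele``.
    """

    amplicon_position: int
    kind: str  # "substitution" | "insertion" | "deletion"
    ref_allele: str
    alt_allele: str
    roi_labels: tuple[str, ...] = ()

    def notation(self) -> str:
        ref = self.ref_allele or "-"
        alt = self.alt_allele or "-"
        return f"{self.amplicon_position}:{ref}>{alt}"


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_semiglobal(
    query: str, reference: str, scoring: Scoring = DEFAULT_SCORING
) -> AlignmentResult:
    """Optimal affine-gap alignment with free end-gaps on the reference.

    Traceback is deterministic: on equal scores the preference order is
    match/mismatch, then deletion, then insertion, and among equal-scoring
    end points the leftmost reference end is used.
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    score, end_i, state, del_open, ins_open = semiglobal_dp(
        _as_bytes(reference),
        _as_bytes(query),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    ops: list[tuple[str, int]] = []

    def push(op: str) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    i, j = int(end_i), len(query)
    while True:
        st = state[i, j]
        if st == ST_FREE:
            break
        if st == ST_DIAG:
            push("match" if reference[i - 1] == query[j - 1] else "mismatch")
            i -= 1
            j -= 1
        elif st == ST_DEL:
            while True:
                push("deletion")
                opened = del_open[i, j]
                i -= 1
                if opened:
                    break
        else:  # ST_INS
            while True:
                push("insertion")
                opened = ins_open[i, j]
                j -= 1
                if opened:
                    break
        if j == 0 and state[i, j] == ST_FREE:
            break
    ops.reverse()
    return AlignmentResult(
        operations=tuple(ops),
        score=int(score),
        query=query,
        ref_start=i,
        ref_end=int(end_i),
    )


def align_fragment(
    query: str, locus: TargetLocus, scoring: Scoring = DEFAULT_SCORING
) -> AlignmentResult:
    """Align a fragment in both orientations and keep the better one.

    Library orientation is normally resolved at demultiplexing; trying the
    reverse complement guards against swapped primer files.  Forward wins
    score ties.
    """
    fwd = align_semiglobal(query, locus.reference_amplicon, scoring)
    rev = align_semiglobal(revcomp(query), locus.reference_amplicon, scoring)
    if rev.score > fwd.score:
        return AlignmentResult(
            operations=rev.operations,
            score=rev.score,
            query=rev.query,
            ref_start=rev.ref_start,
            ref_end=rev.ref_end,
            strand="-",
        )
    return fwd


# ---------------------------------------------------------------------------
# variants


def _roi_overlap(
    locus: TargetLocus, span_start: int, span_end: int
) -> tuple[str, ...]:
    return tuple(
        label
        for label, s, e in locus.regions_of_interest
        if max(s, span_start) < min(e, span_end)
    )


def left_align(variant: Variant, reference: str) -> Variant:
    """Shift an indel to its leftmost equivalent placement."""
    pos = variant.amplicon_position
    if variant.kind == "deletion":
        k = len(variant.ref_allele)
        while pos > 0 and reference[pos - 1] == reference[pos + k - 1]:
            pos -= 1
        return Variant(pos, "deletion", reference[pos : pos + k], "", variant.roi_labels)
    if variant.kind == "insertion":
        alt = variant.alt_allele
        while pos > 0 and reference[pos - 1] == alt[-1]:
            alt = reference[pos - 1] + alt[:-1]
            pos -= 1
        return Variant(pos, "insertion", "", alt, variant.roi_labels)
    return variant


def extract_variants(alignment: AlignmentResult, locus: TargetLocus) -> list[Variant]:
    """Read left-aligned variants off an alignment.

    Mismatch runs are reported base-by-base (matching the donor-diff
    representation); gap runs become single indel records.  Each variant
    carries the labels of any regions of interest it touches.
    """
    ref = locus.reference_amplicon
    variants: list[Variant] = []
    i = alignment.ref_start
    j = 0
    q = alignment.query
    for op, n in alignment.operations:
        if op == "match":
            i += n
            j += n
        elif op == "mismatch":
            for k in range(n):
                variants.append(
                    Variant(i + k, "substitution", ref[i + k], q[j + k])
                )
            i += n
            j += n
        elif op == "deletion":
            variants.append(left_align(Variant(i, "deletion", ref[i : i + n], ""), ref))
            i += n
        else:  # insertion
            variants.append(left_align(Variant(i, "insertion", "", q[j : j + n]), ref))
            j += n
    variants.sort(key=lambda v: (v.amplicon_position, v.kind))
    annotated = []
    for v in variants:
        if v.kind == "insertion":
            span = (v.amplicon_position, v.amplicon_position + 1)
        else:
            span = (v.amplicon_position, v.amplicon_position + len(v.ref_allele))
        annotated.append(
            Variant(
                v.amplicon_position,
                v.kind,
                v.ref_allele,
                v.alt_allele,
                _roi_overlap(locus, *span),
            )
        )
    return annotated


def apply_variants(reference: str, variants: Sequence[Variant]) -> str:
    """Reconstruct the allele sequence by applying variants to the reference.

    Applied right to left; at a shared position the substitution/deletion
    of the reference base is applied before an insertion in front of it.
    """
    seq = reference
    order = {"substitution": 0, "deletion": 0, "insertion": 1}
    for v in sorted(variants, key=lambda v: (-v.amplicon_position, order[v.kind])):
        p = v.amplicon_position
        if v.kind == "substitution":
            seq = seq[:p] + v.alt_allele + seq[p + 1 :]
        elif v.kind == "deletion":
            seq = seq[:p] + seq[p + len(v.ref_allele) :]
        else:
            seq = seq[:p] + v.alt_allele + seq[p:]
    return seq


def donor_haplotype(locus: TargetLocus) -> str:
    """The reference amplicon with all donor substitutions applied."""
    if not locus.donor_diffs:
        raise ValueError(f"locus {locus.name} declares no donor substitutions")
    seq = list(locus.reference_amplicon)
    for pos, _ref, alt in locus.donor_diffs:
        seq[pos] = alt
    return "".join(seq)


def classify_allele(
    variants: list[Variant],
    locus: TargetLocus,
    scoring: Scoring = DEFAULT_SCORING,
) -> AlleleClass:
    """Classify one allele relative to the programmed edit (see module docs).

    When an indel sits next to the donor base the optimal alignment can
    represent the same allele with or without a donor-position
    substitution (equal scores, different variant lists), so donor
    presence cannot be read off one variant list.  In that case the
    allele sequence is reconstructed and re-aligned against the donor
    haplotype: the donor edit is present iff the allele aligns strictly
    better to the donor haplotype than to the reference.
    """
    if not variants:
        return AlleleClass.WT
    donor = set(locus.donor_diffs or ())
    observed_subs = {
        (v.amplicon_position, v.ref_allele, v.alt_allele)
        for v in variants
        if v.kind == "substitution"
    }
    has_indel = any(v.kind in ("insertion", "deletion") for v in variants)
    if not donor:
        return AlleleClass.NHEJ_INDEL if has_indel else AlleleClass.SUBSTITUTION_ONLY
    if not has_indel:
        # substitution-only variant lists are representation-unique
        if observed_subs == donor:
            return AlleleClass.HDR
        if donor <= observed_subs:
            return AlleleClass.COMPLEX
        return AlleleClass.SUBSTITUTION_ONLY
    allele_seq = apply_variants(locus.reference_amplicon, variants)
    vs_ref = align_semiglobal(allele_seq, locus.reference_amplicon, scoring).score
    vs_donor = align_semiglobal(allele_seq, donor_haplotype(locus), scoring).score
    return AlleleClass.COMPLEX if vs_donor > vs_ref else AlleleClass.NHEJ_INDEL


# ---------------------------------------------------------------------------
# design checks


@dataclass(frozen=True)
class DesignNote:
    level: str  # "warning" | "note"
    message: str


def validate_amplicon_design(
    primer_fwd_offset: int,
    primer_rev_offset: int,
    edit_position: int,
    product_length: int,
    heterozygous_snp_declared: bool = False,
) -> list[DesignNote]:
    """Check primer placement against amplicon design guidelines.

    Primers should sit 150-200 bp from the editing site so the product is
    300-400 bp: short enough for overlapping 250 bp mates to reconstruct
    it, long enough that a large deletion removing a primer site (the
    false-homozygote failure mode) is unlikely to go unnoticed.  When no
    heterozygous SNP is declared inside the amplicon, a note reminds the
    user that apparent homozygotes cannot be distinguished from loss of
    one allele's primer site.
    """
    notes: list[DesignNote] = []
    d_fwd = edit_position - primer_fwd_offset
    d_rev = primer_rev_offset - edit_position
    for name, d in (("forward", d_fwd), ("reverse", d_rev)):
        if d < 150:
            notes.append(
                DesignNote("warning", f"{name} primer only {d} bp from edit site (<150)")
            )
        elif d > 200:
            notes.append(
                DesignNote("warning", f"{name} primer {d} bp from edit site (>200)")
            )
    if product_length < 300:
        notes.append(DesignNote("warning", f"product {product_length} bp below 300 bp"))
    elif product_length > 400:
        notes.append(
            DesignNote(
                "warning",
                f"product {product_length} bp above 400 bp; 2x250 bp mates may not overlap",
            )
        )
    if not heterozygous_snp_declared:
        notes.append(
            DesignNote(
                "note",
                "no heterozygous SNP declared in the amplicon: apparent homozygotes "
                "may be false positives caused by a large deletion removing one "
                "allele's primer site",
            )
        )
    return notes
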