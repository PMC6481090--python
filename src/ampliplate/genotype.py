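"""Per-well allele counting and genotype calling.

Merged fragments from one well are collapsed by exact sequence identity
into unique alleles with read counts.  A well is only genotyped when it
reaches the read threshold (default 10 merged fragments); surviving
alleles with at least the minimum fraction of reads are ranked by count
and the top ``ploidy`` of them form the genotype.  A well where a single
allele survives is called homozygous and flagged: without a heterozygous
marker in the amplicon, a large deletion removing one allele's primer
site produces exactly this picture.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .align import (
    DEFAULT_SCORING,
    AlignmentResult,
    AlleleClass,
    Scoring,
    TargetLocus,
    Variant,
    align_fragment,
    classify_allele,
    extract_variants,
)
from .demux import WellAddress
from .merge import MergedFragment

__all__ = [
    "AlleleCount",
    "WellGenotype",
    "PlateSummary",
    "WellStatus",
    "collapse_alleles",
    "call_genotype",
    "success_rate_percent",
    "summarize_plate",
]

DEFAULT_MIN_READS = 10
DEFAULT_MIN_ALLELE_FRACTION = 0.15
DEFAULT_PLOIDY = 2


@dataclass(frozen=True)
class AlleleCount:
    sequence: str
    count: int
    fraction: float
    variants: tuple[Variant, ...]
    allele_class: AlleleClass
    alignment: AlignmentResult


class WellStatus(str, Enum):
    REPORTED = "reported"
    FAILED_LOW_READS = "failed_low_reads"
    EMPTY = "empty"


@dataclass(frozen=True)
class WellGenotype:
    well: WellAddress | None
    total_merged_reads: int
    status: WellStatus
    called_alleles: tuple[AlleleCount, ...]
    genotype_string: str
    homozygote_flag: bool
    all_alleles: tuple[AlleleCount, ...] = ()


@dataclass(frozen=True)
class PlateSummary:
    wells_processed: int
    wells_sequenced: int
    success_rate: float  # percentage, one decimal place


class _AlignmentCache:
    """Alignments keyed by (query, locus name) — identical alleles recur
    across wells, and the wild-type sequence recurs everywhere."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], tuple] = {}

    def annotate(
        self, sequence: str, locus: TargetLocus, scoring: Scoring
    ) -> tuple[AlignmentResult, tuple[Variant, ...], AlleleClass]:
        key = (sequence, locus.name)
        hit = self._store.get(key)
        if hit is None:
            aln = align_fragment(sequence, locus, scoring)
            variants = tuple(extract_variants(aln, locus))
            hit = (aln, variants, classify_allele(list(variants), locus))
            self._store[key] = hit
        return hit


_cache = _AlignmentCache()


def collapse_alleles(
    fragments: Iterable[MergedFragment | str],
    locus: TargetLocus,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[AlleleCount]:
    """Group identical fragment sequences into annotated allele counts.

    Order is deterministic: descending count, then lexicographic sequence.
    Counts conserve the input size exactly and fractions sum to 1.
    """
    seqs = [f if isinstance(f, str) else f.sequence for f in fragments]
    counts = Counter(seqs)
    total = sum(counts.values())
    alleles = []
    for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        aln, variants, klass = _cache.annotate(seq, locus, scoring)
        alleles.append(
            AlleleCount(
                sequence=seq,
                count=n,
                fraction=n / total,
                variants=variants,
                allele_class=klass,
                alignment=aln,
            )
        )
    return alleles


def call_genotype(
    alleles: Sequence[AlleleCount],
    ploidy: int = DEFAULT_PLOIDY,
    min_reads: int = DEFAULT_MIN_READS,
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION,
    well: WellAddress | None = None,
) -> WellGenotype:
    """Call one well's genotype from its ranked allele counts.

    Wells under the read threshold are failed, not called.  Alleles below
    ``min_allele_fraction`` are treated as PCR/sequencing noise; the
    top-fraction allele is always retained so a well never loses all its
    alleles to the filter.  If a single allele survives, the call is that
    class repeated ``ploidy`` times with the homozygote flag set.
    """
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    total = sum(a.count for a in alleles)
    if total == 0:
        return WellGenotype(well, 0, WellStatus.EMPTY, (), "", False)
    if total < min_reads:
        return WellGenotype(
            well, total, WellStatus.FAILED_LOW_READS, (), "", False, tuple(alleles)
        )
    ranked = sorted(alleles, key=lambda a: (-a.count, a.sequence))
    surviving = [a for a in ranked if a.fraction >= min_allele_fraction] or [ranked[0]]
    called = tuple(surviving[:ploidy])
    if len(called) == 1:
        genotype = "/".join([called[0].allele_class.value] * ploidy)
        homozygote = True
    else:
        genotype = "/".join(a.allele_class.value for a in called)
        homozygote = False
    return WellGenotype(
        well, total, WellStatus.REPORTED, called, genotype, homozygote, tuple(ranked)
    )


def success_rate_percent(sequenced: int, processed: int) -> float:
    """Success rate as a percentage truncated to one decimal place.

    Exact integer arithmetic: floor(1000 * sequenced / processed) / 10.
    """
    if processed <= 0:
        raise ValueError("no processed wells: success rate undefined")
    return (1000 * sequenced // processed) / 10


def summarize_plate(wells: Sequence[WellGenotype]) -> PlateSummary:
    """Plate-level success summary over the processed (non-empty) wells.

    The success rate is 100 x sequenced / processed, truncated to one
    decimal place.
    """
    processed = [w for w in wells if w.total_merged_reads > 0]
    if not processed:
        raise ValueError("no processed wells: success rate undefined")
    sequenced = sum(1 for w in processed if w.status is WellStatus.REPORTED)
    rate = success_rate_percent(sequenced, len(processed))
    return PlateSummary(
        wells_processed=len(processed),
        wells_sequenced=sequenced,
        success_rate=rate,
    )
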