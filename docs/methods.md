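# Methods

This note documents the models and conventions behind `ampliplate`: what
each stage computes, the parameters that matter, what the simulator does
and does not emulate, and the numerical choices made where the design
was genuinely open.

## Library model

A sequenced molecule is

```
[GAT spacer + 8 bp row barcode + m13fwd linker] + amplicon allele +
revcomp([GAT spacer + 8 bp column barcode + m13rev linker])
```

read as 2×250 bp mates from either strand with equal probability,
because Illumina adaptor ligation is non-directional.  The default
barcode set is the standard 8-row (iR5_A–H) / 12-column (iC701–712)
plate-screening primer set; its barcodes are mutually distant enough
that any single substitution either corrects uniquely or is rejected as
ambiguous, never reassigned to a different well.  Note the m13fwd linker
embedded in the row primers is the 17 bp variant (`GTAAAACGACGGCCAGT`);
a 16 bp m13fwd spelling also circulates, and the loader derives the
linker from the primer file itself rather than assuming either.

## Demultiplexing

Barcodes are matched in a fixed-offset window after the spacer.  The
window structure is verified in three parts: the 3 bp spacer (≤1
mismatch), the 8 bp barcode (Hamming distance ≤ `max_mismatch`,
default 1, and unique — two qualifying barcodes void the read), and the
first 5 bases of the linker (≤1 mismatch) as a cheap chimera gate.
Failures are classified as `no_spacer`, `too_many_mismatches` or
`ambiguous_barcode`.  Indels in the prefix are deliberately not rescued
by a shifted-window search: the spacer exists to absorb synthesis edge
effects, and a fixed window keeps demultiplexing O(1) per read.

Both mate-role assignments are scored; the orientation with fewer total
barcode mismatches wins and an exact tie leaves the pair unassigned.
On success the full spacer+barcode+linker prefix is trimmed and the
trimmed pair is emitted row-construct-first regardless of ligation
direction, so all fragments of a well share one orientation and
identical alleles collapse together.  Count conservation is exact:
assigned + unassigned = input pairs, for every run.

## Merging ("flashing")

For mates `s1` and `revcomp(s2)` every overlap length from
`min_overlap` (default 10) upward is scanned; the overlap with the
smallest substitution mismatch ratio wins, ties going to the longer
overlap, and ratios are compared by integer cross-multiplication so
there are no floating-point ties.  A best ratio above
`max_mismatch_ratio` (default 0.25) fails the pair with a recorded
reason rather than dropping it silently — relevant for over-long
products, which cannot overlap at 2×250 bp.  Defaults follow the de
facto standard for overlap mergers.  Only substitutions are considered
inside the overlap: both mates read one physical molecule, so true
indels between them cannot occur; indels relative to the reference are
resolved at alignment.  In the consensus the base with the higher Phred
quality wins (tie → mate 1) and the higher quality is kept.

## Alignment and variants

Merged fragments are aligned to the reference amplicon with a Gotoh
affine-gap dynamic program in which the query is aligned end to end
while reference overhangs are free (a truncated fragment aligns to the
amplicon interior).  Scoring defaults: match +1, mismatch −2, gap open
−5, gap extend −1, with a k-base gap costing `open + (k−1)·extend`.
Under this convention a 1 bp indel (−5) beats two substitutions (−6),
the correct prior for Cas9 repair outcomes; with the alternative
`open + k·extend` convention the two would tie and the tie-break would
prefer the substitution representation.  Traceback is deterministic:
diagonal over deletion over insertion on score ties, and the leftmost
reference end point on end ties.  Fragments are also aligned as the
reverse complement and the better orientation kept, guarding against
swapped primer files.  The inner loops are numba-compiled and are
cross-checked in the test suite against an independently written
exhaustive DP on a thousand short instances.

Gap runs are reported as single indel records, left-aligned against the
reference (shift while the flanking base equals the last gap base;
insertions rotate their sequence accordingly); mismatches are reported
base by base, matching the donor-substitution representation.  Variants
are annotated with any overlapping regions of interest from the BED
file (an insertion is attributed to the reference position it precedes).

## Allele classification

Relative to the declared donor substitutions:

| class               | rule                                                       |
|---------------------|------------------------------------------------------------|
| `WT`                | no variants                                                |
| `HDR`               | variants exactly equal the donor substitutions             |
| `NHEJ_indel`        | indel present, donor edit absent                           |
| `substitution_only` | substitutions only, not matching the donor                 |
| `complex`           | donor edit present together with any other change          |

An allele carrying the donor base *and* an indel is `complex`, never
`HDR` — the conservative convention for clone selection.  One subtlety
forces a semantic rather than purely syntactic donor test: when an
indel adjoins the donor base, equal-scoring alignments can represent
the same allele with or without a donor-position substitution.  For
indel-carrying alleles the sequence is therefore reconstructed from its
variants and re-aligned against both the reference and the donor
haplotype; the donor edit counts as present iff the allele aligns
strictly better to the donor haplotype.  For substitution-only alleles
the variant representation is unique and plain set comparison is used.
Without declared donor substitutions `HDR`/`complex` are unreachable
and edited alleles fall into the indel/substitution classes.

## Genotype calling

Fragments collapse into unique alleles by exact sequence identity,
ordered by descending count then sequence.  Calling parameters:

- `min_reads` (default 10, applied to merged fragments — the unit that
  is actually genotyped): below it a well is `failed_low_reads`; with
  zero reads it is `empty` and excluded from the processed count.
- `min_allele_fraction` (default 0.15): suppresses PCR/sequencing noise
  alleles while keeping a four-allele polyploid detectable.  The
  top-count allele is always retained so the filter can never empty a
  well.
- `ploidy` (default 2): the number of alleles reported; a single
  surviving allele is repeated `ploidy` times and the homozygote flag
  set, since true homozygosity is indistinguishable from amplification
  loss of one allele without an internal heterozygous marker.

The plate summary counts processed wells (any merged reads), reported
wells, and the success rate as a percentage **truncated** to one
decimal (`floor(1000·s/p)/10`, exact integer arithmetic).  Truncation
rather than rounding is deliberate: it is the only convention
consistent with all published examples of this screen's summary tables,
three of which fall on truncation/rounding-discriminating values.

## Simulator

The simulator is the test harness for every other module and emulates
the screen's observed regime, not an idealised one.  Per-well genotypes
are drawn from `{WT/WT: 0.25, WT/indel: 0.30, indel/indel: 0.25,
HDR/WT: 0.06, HDR/indel: 0.06, HDR/HDR: 0.03, complex: 0.05}` — NHEJ
dominant, HDR rare, which is the bias that makes the screen necessary.
Indel sizes are geometric with mean 3 bp (deletions twice as likely as
insertions) placed at the cut site ±2 bp; the cut site is the centre of
the first region of interest.  `complex` alleles place their indel
strictly downstream of the donor positions (partial-HDR-plus-indel
repair) and are redrawn in the rare case that the resulting string is
equivalent to a pure insertion of the reference, which would make the
truth label semantically false.  Read depth is log-normal with median
500 pairs per well (σ = 0.8) and 2% of wells are empty, so the
failed-well paths are exercised; substitution errors are i.i.d. at a
configurable rate (default 0.1%), with errored bases assigned low
qualities (Q10–25) and correct bases Q30–40, so the quality-aware
overlap consensus behaves as it does on real data.  A fixed seed makes
the output byte-identical.

Not modelled, hence not demonstrated by passing tests: PCR chimeras and
index hopping, indel-type sequencing errors, quality degradation along
the read, coverage bias between alleles, contamination between wells,
and large deletions extending beyond the amplicon (real screens chase
those with a separate long-range PCR; here they simply present as
false homozygotes, which is why homozygous calls carry a flag).

## Problem sizes used in validation

The shipped checks run on desk-scale data chosen to exercise every code
path: a full 96-well error-free plate at 40 reads/well for exact
end-to-end truth recovery; ten 96-well plates at 200 reads/well and
0.1% substitution error for noise robustness (≥95% of wells must match
truth; in practice all do); 1000 random ≤12 nt instances against the
exhaustive alignment oracle and several hundred ≤60 nt instances
against the exhaustive overlap oracle; and a 1–20 reads/well sweep to
locate the reporting threshold.

## Known limitations

- Exact-sequence allele collapsing means every residual sequencing
  error creates a singleton allele; at very low depth (tens of reads)
  the fraction filter has little material to work with and calls become
  noisy sooner than a clustering collapser would.
- Variants at the extreme amplicon ends can be absorbed into the free
  end-gaps and truncate coverage instead of being reported; primers
  placed 150–200 bp from the edit site (checked by
  `validate_amplicon_design`) keep the editable region well inside the
  amplicon.
- Zygosity is thresholded, not tested statistically; allele fractions
  near the filter boundary are reported as-is.
- One locus per run; multi-locus screens are separate runs over the
  same FASTQ with different primer/BED/reference files.
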