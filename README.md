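# ampliplate

Genotyping of CRISPR/Cas-edited clones from dual-barcoded 96-well
amplicon deep sequencing.

## The problem

Isolating a clone that carries an exact programmed base change is a
numbers game: homology-dependent repair (HDR) is rare relative to
non-homologous end joining (NHEJ), so hundreds of single-cell-sorted
clones must be screened per edit.  A practical screening design
amplifies the edited locus from each well of a 96-well plate
(a 300–400 bp product), barcodes every well in a second PCR round with
one of 8 "row" and one of 12 "column" primers — each a 3 bp spacer, an
8 bp well barcode and an m13-derived linker — pools the plate, and
sequences it as 2×250 bp paired-end reads.  `ampliplate` is the analysis
side of that screen:

1. **Demultiplex** each read pair to a well from its dual barcodes
   (both mate orientations tried; ambiguous pairs are discarded, the
   spacer+barcode+linker prefix is trimmed).
2. **Merge** overlapping mates back into the original amplicon fragment
   (minimum-mismatch-ratio overlap, quality-weighted consensus).
3. **Align** each fragment to the reference amplicon with an affine-gap
   semi-global aligner (free reference end-gaps, match +1, mismatch −2,
   gap open −5, gap extend −1), extract left-aligned variants, and
   classify every allele as `WT`, `HDR`, `NHEJ_indel`,
   `substitution_only` or `complex` relative to the declared donor
   substitutions.
4. **Call genotypes** per well: unique alleles are counted, wells with
   fewer than 10 merged reads are failed, noise alleles below 15% of
   reads are dropped, and the top `ploidy` alleles form the genotype
   string (e.g. `HDR/NHEJ_indel`).  Wells where a single allele
   survives are flagged as homozygous calls, which deserve scrutiny: a
   large deletion removing one allele's primer site produces the same
   picture.
5. **Report** a plate summary (wells processed, successfully sequenced,
   success rate), per-well allele tables, and a rendered text alignment
   of each called allele with regions of interest highlighted.

A seeded plate **simulator** generates paired FASTQ with a known truth
table (library molecule = row construct + allele + reverse-complemented
column construct, strand-randomised reads, substitution errors,
log-normal read depth), so the whole pipeline can be validated end to
end.

## Worked example

Simulate a plate and analyse it:

```bash
ampliplate simulate --out demo --seed 11 --wells 96 --error-rate 0.001
# simulated 96 wells, 76925 read pairs

ampliplate run \
    --fastq-list demo/fastq_paths.txt \
    --fwd-primers demo/spacerBarcodePrimer_FWD.txt \
    --rev-primers demo/spacerBarcodePrimer_REV.txt \
    --bed demo/targetLocus.bed \
    --reference demo/reference.fa \
    --donor demo/donor_diffs.txt \
    --out demo/out
```

The run logs per-stage read accounting and prints the plate summary:

```
[ampliplate] demux: 76925 pairs total, 76921 assigned+merged, 0 assigned but unmerged, 4 unassigned
[ampliplate] genotyping: 94 wells processed, 94 reported (100.0%)
wells processed: 94	successfully sequenced: 94	success rate: 100.0%
```

(94, not 96: two wells were simulated empty, mimicking failed lysis.)
`demo/out/wells.tsv` then holds one call per well:

```
well	status	total_reads	genotype	homozygote_flag	n_called_alleles
A01	reported	328	HDR/NHEJ_indel	0	2
A02	reported	458	complex/WT	0	2
A03	reported	329	WT/WT	1	1
```

Well A01 is a compound heterozygote: one allele carries the programmed
substitution (`HDR`, variant `175:A>C`, 38% of reads) and the other a
2 bp deletion at the cut site (`NHEJ_indel`, `175:AA>-`, 36%); the rest
are low-frequency sequencing-noise alleles that the fraction filter
removed.  `demo/out/report.txt` renders each called allele against the
reference with the gRNA/edit-site columns marked, and
`demo/out/alleles.tsv` lists every observed allele with count, fraction
and variant notation.

The same analysis runs on real MiSeq data given the two primer files,
the locus BED, the reference amplicon FASTA and (optionally) the donor
substitutions; see `ampliplate run --help`.

## Layout

- `src/ampliplate/demux.py` — barcode scheme, per-pair and per-run demultiplexing
- `src/ampliplate/merge.py` — overlap search and pair merging
- `src/ampliplate/align.py` — semi-global aligner, variants, allele classification, design checks
- `src/ampliplate/genotype.py` — allele collapsing, genotype calls, plate summary
- `src/ampliplate/report.py` — text alignments and TSV/plain-text/HTML reports
- `src/ampliplate/simulate.py` — seeded plate simulator with truth table
- `src/ampliplate/io.py`, `pipeline.py`, `cli.py` — file formats, the pipeline driver and the CLI
- `docs/methods.md` — models, parameters, numerical conventions and limitations
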