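"""Synthetic 96-well plate simulator with a known truth table.

Emulates the library molecule produced by two rounds of PCR:

    [GAT + row barcode + m13fwd linker] + allele + revcomp([GAT + column
    barcode + m13rev linker])

read as 2 x 250 bp mates from either strand with equal probability
(adaptor ligation is non-directional).  Per-well genotypes are drawn
from a distribution in which NHEJ indels dominate and HDR is rare,
matching the repair-pathway bias the screen exists to overcome.  Errors
are i.i.d. substitutions (the dominant MiSeq error mode); PCR chimeras
and index hopping are not modelled.

Every simulated plate ships with its truth table and the plain-text
metadata files a real run would use, so a simulation is a complete
end-to-end pipeline fixture.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import TargetLocus
from .demux import BarcodeScheme, ReadPair, WellAddress
from .merge import revcomp
from .primers import default_scheme

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedPlate",
    "random_locus",
    "simulate_allele",
    "build_library_molecule",
    "simulate_reads",
    "simulate_plate",
    "write_plate",
]

#: per-well genotype categories and their default probabilities; HDR-bearing
#: outcomes are deliberately uncommon relative to NHEJ.
DEFAULT_GENOTYPE_PROBABILITIES: dict[str, float] = {
    "WT/WT": 0.25,
    "WT/indel": 0.30,
    "indel/indel": 0.25,
    "HDR/WT": 0.06,
    "HDR/indel": 0.06,
    "HDR/HDR": 0.03,
    "complex": 0.05,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated plate.

    ``reads_per_well_median``/``reads_per_well_sigma`` parameterise a
    log-normal read-depth distribution (sigma 0 gives a constant depth);
    ``indel_mean_size`` is the mean of the geometric indel-size
    distribution, with deletions twice as likely as insertions.
    """

    seed: int = 0
    locus: TargetLocus | None = None
    read_length: int = 250
    wells: tuple[str, ...] | None = None  # None -> all wells of the scheme
    genotype_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PROBABILITIES)
    )
    indel_mean_size: float = 3.0
    deletion_fraction: float = 2 / 3
    substitution_error_rate: float = 0.001
    reads_per_well_median: float = 500.0
    reads_per_well_sigma: float = 0.8
    empty_well_probability: float = 0.02
    cut_jitter: int = 2

    def __post_init__(self) -> None:
        total = sum(self.genotype_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class TruthRecord:
    well: str
    allele_sequences: tuple[str, ...]
    allele_classes: tuple[str, ...]
    genotype_string: str  # classes sorted alphabetically, joined with "/"
    reads_emitted: int


@dataclass
class SimulatedPlate:
    config: SimConfig
    scheme: BarcodeScheme
    locus: TargetLocus
    pairs: list[ReadPair]
    truth: list[TruthRecord]


def random_locus(
    seed: int = 0,
    length: int = 350,
    name: str = "synthetic_locus",
    chrom: str = "chrS",
    start: int = 10_000,
) -> TargetLocus:
    """A random amplicon with a central 20 bp gRNA region and a donor SNV.

    The cut site sits at the amplicon midpoint (3 bp into the gRNA's
    PAM-proximal end in a real design; here simply the ROI centre) and
    the donor substitution converts the base at the midpoint.
    """
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    mid = length // 2
    ref_base = seq[mid]
    donor_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
    return TargetLocus(
        name=name,
        chrom=chrom,
        start=start,
        end=start + length,
        reference_amplicon=seq,
        regions_of_interest=(("gRNA", mid - 10, mid + 10), ("edit_site", mid, mid + 1)),
        donor_diffs=((mid, ref_base, donor_base),),
    )


def _cut_site(locus: TargetLocus) -> int:
    if not locus.regions_of_interest:
        raise ValueError("locus needs a region of interest to place the cut site")
    label, s, e = locus.regions_of_interest[0]
    return (s + e) // 2


def sample_indel_size(config: SimConfig, rng: np.random.Generator) -> int:
    """Geometric indel size (support >= 1) with the configured mean."""
    return int(rng.geometric(1.0 / config.indel_mean_size))


def _apply_indel(seq: str, cut: int, config: SimConfig, rng: np.random.Generator) -> str:
    size = sample_indel_size(config, rng)
    pos = cut + int(rng.integers(-config.cut_jitter, config.cut_jitter + 1))
    pos = max(1, min(pos, len(seq) - 2))
    if rng.random() < config.deletion_fraction:
        end = min(pos + size, len(seq) - 1)
        return seq[:pos] + seq[end:]
    insert = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
    return seq[:pos] + insert + seq[pos:]


def _apply_donor(locus: TargetLocus) -> str:
    if not locus.donor_diffs:
        raise ValueError("HDR outcome requested but the locus has no donor substitutions")
    seq = list(locus.reference_amplicon)
    for pos, _ref, alt in locus.donor_diffs:
        seq[pos] = alt
    return "".join(seq)


def simulate_allele(locus: TargetLocus, outcome: str, rng: np.random.Generator) -> str:
    """One allele sequence for an intended repair outcome.

    outcome: "WT", "HDR", "NHEJ_indel" (indel at the cut site +- jitter)
    or "complex" (donor substitution plus an indel).
    """
    if outcome == "WT":
        return locus.reference_amplicon
    if outcome == "HDR":
        return _apply_donor(locus)
    cut = _cut_site(locus)
    config = SimConfig(locus=locus)
    if outcome == "NHEJ_indel":
        return _apply_indel(locus.reference_amplicon, cut, config, rng)
    if outcome == "complex":
        # donor substitution plus an indel; the indel is placed strictly
        # downstream of every donor position so the programmed base change
        # survives (partial-HDR-plus-indel repair, not re-cut loss).  A
        # drawn indel can occasionally make the whole allele string-equal
        # to a pure insertion of the reference, erasing the donor edit
        # from the sequence itself; such draws are rejected so the truth
        # label stays semantically meaningful.
        from .align import align_semiglobal, donor_haplotype

        donor_seq = _apply_donor(locus)
        hap = donor_haplotype(locus)
        shifted_cut = max(cut, max(p for p, _, _ in locus.donor_diffs) + 1 + config.cut_jitter)
        for _ in range(50):
            allele = _apply_indel(donor_seq, shifted_cut, config, rng)
            vs_ref = align_semiglobal(allele, locus.reference_amplicon).score
            vs_donor = align_semiglobal(allele, hap).score
            if vs_donor > vs_ref:
                return allele
        raise RuntimeError("could not draw a sequence-distinguishable complex allele")
    raise ValueError(f"unknown outcome {outcome!r}")


_GENOTYPE_ALLELES: dict[str, tuple[str, str]] = {
    "WT/WT": ("WT", "WT"),
    "WT/indel": ("WT", "NHEJ_indel"),
    "indel/indel": ("NHEJ_indel", "NHEJ_indel"),
    "HDR/WT": ("HDR", "WT"),
    "HDR/indel": ("HDR", "NHEJ_indel"),
    "HDR/HDR": ("HDR", "HDR"),
    "complex": ("complex", "WT"),
}

_OUTCOME_CLASS: dict[str, str] = {
    "WT": "WT",
    "HDR": "HDR",
    "NHEJ_indel": "NHEJ_indel",
    "complex": "complex",
}


def build_library_molecule(
    allele: str, well: WellAddress, scheme: BarcodeScheme
) -> str:
    """The barcoded second-round PCR product for one allele in one well."""
    row = scheme.row_primers["ABCDEFGH".index(well.row)]
    col = scheme.column_primers[well.column - 1]
    return row.full_sequence + allele + revcomp(col.full_sequence)


def _mutate(
    seq: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Apply i.i.d. substitution errors; return (sequence, quality string).

    Correct bases get Q30-class qualities, errored bases lower ones, so
    the overlap consensus behaves like a real quality-aware merger.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.shape[0]
    quals = rng.integers(30, 41, size=n)
    if error_rate > 0:
        hits = np.nonzero(rng.random(n) < error_rate)[0]
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, choices.shape[0])]
        quals[hits] = rng.integers(10, 26, size=hits.shape[0])
    qual = (quals + 33).astype(np.uint8).tobytes().decode("ascii")
    return arr.tobytes().decode("ascii"), qual


def simulate_reads(
    molecule: str,
    n_pairs: int,
    config: SimConfig,
    rng: np.random.Generator,
    pair_prefix: str = "sim",
) -> list[ReadPair]:
    """Paired 250 bp reads of one molecule, strand randomised per pair."""
    L = config.read_length
    pairs = []
    for k in range(n_pairs):
        template = molecule if rng.random() < 0.5 else revcomp(molecule)
        m1 = template[:L]
        m2 = revcomp(template[-L:])
        s1, q1 = _mutate(m1, config.substitution_error_rate, rng)
        s2, q2 = _mutate(m2, config.substitution_error_rate, rng)
        pairs.append(ReadPair(id=f"{pair_prefix}:{k}", seq1=s1, qual1=q1, seq2=s2, qual2=q2))
    return pairs


def _reads_for_well(config: SimConfig, rng: np.random.Generator) -> int:
    if config.empty_well_probability > 0 and rng.random() < config.empty_well_probability:
        return 0
    if config.reads_per_well_sigma == 0:
        return max(1, int(round(config.reads_per_well_median)))
    n = rng.lognormal(np.log(config.reads_per_well_median), config.reads_per_well_sigma)
    return max(1, int(round(n)))


def simulate_plate(
    config: SimConfig, scheme: BarcodeScheme | None = None
) -> SimulatedPlate:
    """Simulate a whole plate; reads are interleaved in random order.

    The minimum mergeable-overlap constraint bounds molecule length at
    2 x read_length - 10; over-long molecules (an over-long allele) are
    skipped with a warning rather than emitted unmergeable.
    """
    import warnings

    scheme = scheme or default_scheme()
    locus = config.locus or random_locus(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    wells = (
        [scheme.address_of(w) for w in config.wells]
        if config.wells is not None
        else scheme.wells()
    )
    categories = sorted(config.genotype_probabilities)
    probs = np.array([config.genotype_probabilities[c] for c in categories])
    probs = probs / probs.sum()

    truth: list[TruthRecord] = []
    all_pairs: list[ReadPair] = []
    max_len = 2 * config.read_length - 10
    for well in wells:
        category = categories[int(rng.choice(len(categories), p=probs))]
        outcomes = _GENOTYPE_ALLELES[category]
        alleles = tuple(simulate_allele(locus, o, rng) for o in outcomes)
        classes = tuple(_OUTCOME_CLASS[o] for o in outcomes)
        n_reads = _reads_for_well(config, rng)
        emitted = 0
        molecules = [build_library_molecule(a, well, scheme) for a in alleles]
        usable = [i for i, m in enumerate(molecules) if len(m) <= max_len]
        for i, m in enumerate(molecules):
            if i not in usable:
                warnings.warn(
                    f"well {well.label}: molecule of {len(m)} bp exceeds the "
                    f"mergeable maximum {max_len} bp; skipped"
                )
        if n_reads > 0 and usable:
            picks = rng.integers(0, len(usable), size=n_reads)
            for k, pick in enumerate(picks):
                mol = molecules[usable[int(pick)]]
                all_pairs.extend(
                    simulate_reads(mol, 1, config, rng, pair_prefix=f"sim:{well.label}:{k}")
                )
            emitted = n_reads
        truth.append(
            TruthRecord(
                well=well.label,
                allele_sequences=alleles,
                allele_classes=classes,
                genotype_string="/".join(sorted(classes)),
                reads_emitted=emitted,
            )
        )
    order = rng.permutation(len(all_pairs))
    all_pairs = [all_pairs[i] for i in order]
    return SimulatedPlate(config=config, scheme=scheme, locus=locus, pairs=all_pairs, truth=truth)


# ---------------------------------------------------------------------------
# fixture output


def write_plate(plate: SimulatedPlate, out_dir: str | Path, compress: bool = True) -> dict[str, Path]:
    """Write FASTQ + truth + metadata files for a simulated plate.

    Produces everything a real analysis run needs: the paired FASTQ, the
    fastq path list, forward/reverse barcode primer files, the target
    locus BED and reference amplicon FASTA, the donor-substitution file,
    and the truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if compress else ".fastq"
    r1 = out / f"plate_R1{suffix}"
    r2 = out / f"plate_R2{suffix}"
    opener = gzip.open if compress else open
    with opener(r1, "wt") as f1, opener(r2, "wt") as f2:
        for p in plate.pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")

    paths = {"fastq1": r1, "fastq2": r2}

    fastq_list = out / "fastq_paths.txt"
    fastq_list.write_text(f"{r1.name}\t{r2.name}\n")  # relative to the list file
    paths["fastq_list"] = fastq_list

    fwd = out / "spacerBarcodePrimer_FWD.txt"
    fwd.write_text("".join(f"{p.id}\t{p.full_sequence}\n" for p in plate.scheme.row_primers))
    rev = out / "spacerBarcodePrimer_REV.txt"
    rev.write_text("".join(f"{p.id}\t{p.full_sequence}\n" for p in plate.scheme.column_primers))
    paths["fwd_primers"] = fwd
    paths["rev_primers"] = rev

    locus = plate.locus
    bed = out / "targetLocus.bed"
    lines = [f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.name}\n"]
    for label, s, e in locus.regions_of_interest:
        lines.append(f"{locus.chrom}\t{locus.start + s}\t{locus.start + e}\t{label}\n")
    bed.write_text("".join(lines))
    paths["bed"] = bed

    fasta = out / "reference.fa"
    seq = locus.reference_amplicon
    wrapped = "\n".join(seq[i : i + 70] for i in range(0, len(seq), 70))
    fasta.write_text(f">{locus.name}\n{wrapped}\n")
    paths["reference"] = fasta

    if locus.donor_diffs:
        donor = out / "donor_diffs.txt"
        donor.write_text(
            "".join(f"{pos}\t{ref}\t{alt}\n" for pos, ref, alt in locus.donor_diffs)
        )
        paths["donor"] = donor

    truth = out / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("well\tgenotype\tclasses\treads\talleles\n")
        for rec in plate.truth:
            fh.write(
                f"{rec.well}\t{rec.genotype_string}\t{','.join(rec.allele_classes)}\t"
                f"{rec.reads_emitted}\t{','.join(rec.allele_sequences)}\n"
            )
    paths["truth"] = truth
    return paths
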