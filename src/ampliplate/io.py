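"""File formats and run configuration.

All metadata inputs are plain text, mirroring the field's convention for
this kind of screen: a fastq path list, two barcode-primer files, a BED
file giving the amplicon interval and regions of interest, a reference
amplicon FASTA, and an optional donor-substitution file.  Coordinates
are 0-based half-open throughout.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import TargetLocus
from .demux import FormatError, ReadPair

__all__ = [
    "RunConfig",
    "read_fastq_pairs",
    "read_fastq_list",
    "read_target_bed",
    "read_reference_fasta",
    "read_donor_diffs",
    "load_locus",
    "read_config",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r", newline=None)


def _clean_id(title: str) -> str:
    rid = title.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def read_fastq_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    """Stream mate-paired reads from two FASTQ files (gzip transparent).

    Mates must appear in matching order; a count mismatch between the two
    files raises an input error.
    """
    with _open_text(fastq1) as f1, _open_text(fastq2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FormatError(
                    f"mate count mismatch between {fastq1} and {fastq2}"
                )
            t1, s1, q1 = r1
            t2, s2, q2 = r2
            yield ReadPair(
                id=_clean_id(t1), seq1=s1.upper(), qual1=q1, seq2=s2.upper(), qual2=q2
            )


def read_fastq_list(path: str | Path) -> list[tuple[Path, Path]]:
    """Parse the fastq path list: one 'R1<TAB>R2' (or whitespace) pair per line."""
    pairs = []
    base = Path(path).parent
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected two fastq paths, got {line!r}")
        p1, p2 = (Path(f) for f in fields)
        if not p1.is_absolute():
            p1 = base / p1
        if not p2.is_absolute():
            p2 = base / p2
        pairs.append((p1, p2))
    return pairs


def read_target_bed(path: str | Path):
    """Parse the target-locus BED file (0-based half-open).

    The first line is the amplicon interval; any further lines are regions
    of interest, returned in amplicon-relative coordinates.
    Returns (name, chrom, start, end, rois).
    """
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >=3 columns, got {line!r}")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"region{lineno}"
        if end <= start:
            raise FormatError(f"{path}:{lineno}: empty/inverted interval")
        intervals.append((chrom, start, end, name))
    if not intervals:
        raise FormatError(f"{path}: no intervals found")
    chrom, start, end, name = intervals[0]
    rois = []
    for rchrom, rstart, rend, rname in intervals[1:]:
        if rchrom != chrom or rstart < start or rend > end:
            raise FormatError(
                f"{path}: region {rname} ({rchrom}:{rstart}-{rend}) outside the "
                f"amplicon interval {chrom}:{start}-{end}"
            )
        rois.append((rname, rstart - start, rend - start))
    return name, chrom, start, end, tuple(rois)


def read_reference_fasta(path: str | Path) -> tuple[str, str]:
    """First record of a FASTA file as (name, uppercase sequence)."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            return record.id, str(record.seq).upper()
    raise FormatError(f"{path}: no FASTA records")


def read_donor_diffs(path: str | Path) -> tuple[tuple[int, str, str], ...]:
    """Donor substitutions, one per line: 'pos ref alt' or 'pos:ref>alt'.

    Positions are 0-based amplicon coordinates.
    """
    diffs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" in line and ">" in line:
            pos_s, rest = line.split(":", 1)
            ref, alt = rest.split(">", 1)
        else:
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'pos ref alt'")
            pos_s, ref, alt = fields
        diffs.append((int(pos_s), ref.strip().upper(), alt.strip().upper()))
    return tuple(diffs)


def load_locus(
    bed: str | Path,
    reference_fasta: str | Path,
    donor: str | Path | None = None,
) -> TargetLocus:
    """Assemble a TargetLocus from the BED, reference FASTA and donor files."""
    name, chrom, start, end, rois = read_target_bed(bed)
    _, seq = read_reference_fasta(reference_fasta)
    if len(seq) != end - start:
        raise FormatError(
            f"reference amplicon is {len(seq)} bp but BED interval is {end - start} bp"
        )
    donor_diffs = read_donor_diffs(donor) if donor else None
    return TargetLocus(
        name=name,
        chrom=chrom,
        start=start,
        end=end,
        reference_amplicon=seq,
        regions_of_interest=rois,
        donor_diffs=donor_diffs,
    )


@dataclass
class RunConfig:
    """Everything one analysis run needs; mirrors the CLI flags."""

    fastq_list: Path
    fwd_primers: Path
    rev_primers: Path
    bed: Path
    reference: Path
    donor: Path | None = None
    out_dir: Path = Path("ampliplate_out")
    max_mismatch: int = 1
    min_overlap: int = 10
    max_mismatch_ratio: float = 0.25
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1
    min_reads: int = 10
    min_allele_fraction: float = 0.15
    ploidy: int = 2
    write_html: bool = False

    def validate(self) -> None:
        for attr in ("fastq_list", "fwd_primers", "rev_primers", "bed", "reference"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.donor is not None and not Path(self.donor).exists():
            raise FileNotFoundError(f"donor file not found: {self.donor}")

    def parameters(self) -> dict:
        return {
            "max_mismatch": self.max_mismatch,
            "min_overlap": self.min_overlap,
            "max_mismatch_ratio": self.max_mismatch_ratio,
            "match": self.match,
            "mismatch": self.mismatch,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "min_reads": self.min_reads,
            "min_allele_fraction": self.min_allele_fraction,
            "ploidy": self.ploidy,
        }


_CONFIG_PATHS = {"fastq_list", "fwd_primers", "rev_primers", "bed", "reference", "donor", "out_dir"}
_CONFIG_INTS = {"max_mismatch", "min_overlap", "match", "mismatch", "gap_open", "gap_extend", "min_reads", "ploidy"}
_CONFIG_FLOATS = {"max_mismatch_ratio", "min_allele_fraction"}


def read_config(path: str | Path) -> RunConfig:
    """Read a plain key = value configuration file into a RunConfig.

    Relative paths are resolved against the config file's directory.
    """
    base = Path(path).parent
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key in _CONFIG_PATHS:
            p = Path(val)
            values[key] = p if p.is_absolute() else base / p
        elif key in _CONFIG_INTS:
            values[key] = int(val)
        elif key in _CONFIG_FLOATS:
            values[key] = float(val)
        elif key == "write_html":
            values[key] = val.lower() in ("1", "true", "yes")
        else:
            raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
    missing = {"fastq_list", "fwd_primers", "rev_primers", "bed", "reference"} - set(values)
    if missing:
        raise FormatError(f"{path}: missing required keys: {sorted(missing)}")
    return RunConfig(**values)
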