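"""Dual-barcode demultiplexing of paired-end amplicon reads.

Every well of a 96-well plate is addressed by a (row, column) pair of
barcode primers.  Library molecules carry the row construct
``spacer + row barcode + row linker`` on one end and the reverse
complement of the column construct on the other; because Illumina
adaptor ligation is non-directional, either mate of a read pair may
carry either construct, so both mate-role assignments are tried.

Barcodes are matched in a fixed-offset window directly after the spacer.
Indels in the prefix are deliberately not rescued with a shifted-window
search: the spacer exists to absorb synthesis edge effects and the fixed
window keeps demultiplexing O(1) per read.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "FormatError",
    "SequenceError",
    "SchemeError",
    "Group",
    "FailReason",
    "Orientation",
    "BarcodePrimer",
    "BarcodeScheme",
    "WellAddress",
    "ReadPair",
    "DemuxAssignment",
    "DemuxResult",
    "load_scheme",
    "scheme_from_primers",
    "assign_barcode",
    "demultiplex_pair",
    "demultiplex_run",
]

DNA_ALPHABET = frozenset("ACGT")

# first bases of the linker checked as a sanity gate against chimeric or
# unstructured prefixes
LINKER_GATE_LENGTH = 5
LINKER_GATE_MAX_MISMATCH = 1
SPACER_MAX_MISMATCH = 1


class FormatError(ValueError):
    """A metadata file is not the expected plain-text format."""


class SequenceError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


class SchemeError(ValueError):
    """The primer set does not form a valid barcode scheme."""


class Group(str, Enum):
    ROW = "row"
    COLUMN = "column"


class FailReason(str, Enum):
    NONE = "none"
    NO_SPACER = "no_spacer"
    AMBIGUOUS_BARCODE = "ambiguous_barcode"
    TOO_MANY_MISMATCHES = "too_many_mismatches"


class Orientation(str, Enum):
    ROW_FIRST = "row_first"
    COLUMN_FIRST = "column_first"
    NONE = "none"


@dataclass(frozen=True)
class BarcodePrimer:
    """One barcoding primer decomposed into spacer / barcode / linker."""

    id: str
    group: Group
    spacer: str
    barcode: str
    linker: str

    @property
    def full_sequence(self) -> str:
        return self.spacer + self.barcode + self.linker


@dataclass(frozen=True)
class WellAddress:
    """A plate position such as row ``A``, column 1 -> label ``A01``."""

    row: str
    column: int

    @property
    def label(self) -> str:
        return f"{self.row}{self.column:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch for read {self.id!r}")


ROW_LETTERS = "ABCDEFGH"


@dataclass(frozen=True)
class BarcodeScheme:
    """The full dual-barcode layout of a plate.

    Row primers map to plate rows in file order (A, B, C, ...) and column
    primers to columns (1, 2, 3, ...); with the standard 8 + 12 set this
    yields the 96 well addresses A01..H12.
    """

    row_primers: tuple[BarcodePrimer, ...]
    column_primers: tuple[BarcodePrimer, ...]

    def __post_init__(self) -> None:
        for group, primers in ((Group.ROW, self.row_primers), (Group.COLUMN, self.column_primers)):
            barcodes = [p.barcode for p in primers]
            if len(set(barcodes)) != len(barcodes):
                raise SchemeError(f"duplicate barcode in {group.value} group")
            if len({p.linker for p in primers}) > 1:
                raise SchemeError(f"linker differs within {group.value} group")
        all_primers = self.row_primers + self.column_primers
        if len({p.spacer for p in all_primers}) > 1:
            raise SchemeError("spacer differs between primers")
        if len({len(p.barcode) for p in all_primers}) > 1:
            raise SchemeError("barcode lengths differ within scheme")

    @property
    def spacer(self) -> str:
        return self.row_primers[0].spacer

    @property
    def row_linker(self) -> str:
        return self.row_primers[0].linker

    @property
    def column_linker(self) -> str:
        return self.column_primers[0].linker

    @property
    def barcode_length(self) -> int:
        return len(self.row_primers[0].barcode)

    @property
    def n_wells(self) -> int:
        return len(self.row_primers) * len(self.column_primers)

    def primers(self, group: Group) -> tuple[BarcodePrimer, ...]:
        return self.row_primers if group is Group.ROW else self.column_primers

    def well_for(self, row_primer_id: str, column_primer_id: str) -> WellAddress:
        ri = [p.id for p in self.row_primers].index(row_primer_id)
        ci = [p.id for p in self.column_primers].index(column_primer_id)
        return WellAddress(row=ROW_LETTERS[ri], column=ci + 1)

    def wells(self) -> list[WellAddress]:
        return [
            WellAddress(row=ROW_LETTERS[ri], column=ci + 1)
            for ri in range(len(self.row_primers))
            for ci in range(len(self.column_primers))
        ]

    def address_of(self, label: str) -> WellAddress:
        return WellAddress(row=label[0], column=int(label[1:]))


@dataclass(frozen=True)
class DemuxAssignment:
    pair_id: str
    well: WellAddress | None
    orientation: Orientation
    mismatches: tuple[int, int]
    trimmed_pair: ReadPair | None
    fail_reason: FailReason

    @property
    def assigned(self) -> bool:
        return self.well is not None


class BarcodeMatch(NamedTuple):
    primer_id: str | None
    mismatches: int
    reason: FailReason


# ---------------------------------------------------------------------------
# scheme loading


def _common_prefix(seqs: list[str]) -> str:
    first, rest = seqs[0], seqs[1:]
    n = len(first)
    for s in rest:
        n = min(n, len(s))
        while first[:n] != s[:n]:
            n -= 1
    return first[:n]


def _common_suffix(seqs: list[str]) -> str:
    return _common_prefix([s[::-1] for s in seqs])[::-1]


def _read_primer_file(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:5] in (b"{\\rtf",) or b"\x00" in raw:
        raise FormatError(f"{path}: not a plain-text file")
    try:
        text = raw.decode("ascii")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: not a plain-text ASCII file") from exc
    entries: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'id sequence', got {line!r}")
        # a three-column layout (id, barcode, full sequence) is also accepted
        entries.append((fields[0], fields[-1].upper()))
    if len(entries) < 2:
        raise FormatError(f"{path}: need at least two primers per group")
    return entries


def scheme_from_primers(
    fwd: list[tuple[str, str]], rev: list[tuple[str, str]]
) -> BarcodeScheme:
    """Decompose raw (id, sequence) primer lists into a scheme.

    The spacer is the longest common prefix over *all* primers; the linker
    of each group is the longest common suffix within that group; the
    barcode is whatever remains in between.
    """
    for pid, seq in fwd + rev:
        if not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise SequenceError(f"primer {pid}: non-ACGT character(s) {bad}")
    all_seqs = [s for _, s in fwd] + [s for _, s in rev]
    spacer = _common_prefix(all_seqs)

    def build(entries: list[tuple[str, str]], group: Group) -> tuple[BarcodePrimer, ...]:
        linker = _common_suffix([s for _, s in entries])
        primers = []
        for pid, seq in entries:
            if len(seq) <= len(spacer) + len(linker):
                raise SchemeError(f"primer {pid}: no barcode between spacer and linker")
            primers.append(
                BarcodePrimer(
                    id=pid,
                    group=group,
                    spacer=spacer,
                    barcode=seq[len(spacer) : len(seq) - len(linker)],
                    linker=linker,
                )
            )
        return tuple(primers)

    return BarcodeScheme(
        row_primers=build(fwd, Group.ROW),
        column_primers=build(rev, Group.COLUMN),
    )


def load_scheme(fwd_primer_file: str | Path, rev_primer_file: str | Path) -> BarcodeScheme:
    """Load the barcode scheme from the two plain-text primer files."""
    return scheme_from_primers(
        _read_primer_file(fwd_primer_file), _read_primer_file(rev_primer_file)
    )


# ---------------------------------------------------------------------------
# per-read assignment


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_barcode(
    read_prefix: str,
    group: Group,
    scheme: BarcodeScheme,
    max_mismatch: int = 1,
) -> BarcodeMatch:
    """Match a read prefix against one barcode group.

    Returns the unique barcode whose Hamming distance over the barcode
    window is <= ``max_mismatch``; ambiguous (two qualifying barcodes) and
    distant prefixes yield ``primer_id=None`` with the failure reason.
    The spacer window and the first bases of the linker are each allowed
    one mismatch as a structural gate.
    """
    primers = scheme.primers(group)
    spacer = scheme.spacer
    bl = scheme.barcode_length
    linker = primers[0].linker
    gate = min(LINKER_GATE_LENGTH, len(linker))
    need = len(spacer) + bl + gate
    if len(read_prefix) < need:
        return BarcodeMatch(None, 0, FailReason.NO_SPACER)
    if _hamming(read_prefix[: len(spacer)], spacer) > SPACER_MAX_MISMATCH:
        return BarcodeMatch(None, 0, FailReason.NO_SPACER)
    gate_seq = read_prefix[len(spacer) + bl : need]
    if _hamming(gate_seq, linker[:gate]) > LINKER_GATE_MAX_MISMATCH:
        return BarcodeMatch(None, 0, FailReason.NO_SPACER)

    window = read_prefix[len(spacer) : len(spacer) + bl]
    hits = [(p.id, _hamming(window, p.barcode)) for p in primers]
    qualifying = [h for h in hits if h[1] <= max_mismatch]
    if not qualifying:
        return BarcodeMatch(None, min(d for _, d in hits), FailReason.TOO_MANY_MISMATCHES)
    if len(qualifying) > 1:
        return BarcodeMatch(None, min(d for _, d in qualifying), FailReason.AMBIGUOUS_BARCODE)
    pid, d = qualifying[0]
    return BarcodeMatch(pid, d, FailReason.NONE)


def _trim(pair: ReadPair, row_on_mate1: bool, scheme: BarcodeScheme) -> ReadPair:
    """Trim barcode constructs and canonicalise mate order.

    The returned pair always has the row-construct mate first, so that
    downstream merging yields fragments in one consistent orientation and
    identical alleles collapse together regardless of ligation direction.
    """
    row_cut = len(scheme.spacer) + scheme.barcode_length + len(scheme.row_linker)
    col_cut = len(scheme.spacer) + scheme.barcode_length + len(scheme.column_linker)
    if row_on_mate1:
        s1, q1, s2, q2 = pair.seq1, pair.qual1, pair.seq2, pair.qual2
    else:
        s1, q1, s2, q2 = pair.seq2, pair.qual2, pair.seq1, pair.qual1
    return ReadPair(
        id=pair.id,
        seq1=s1[row_cut:],
        qual1=q1[row_cut:],
        seq2=s2[col_cut:],
        qual2=q2[col_cut:],
    )


def demultiplex_pair(
    pair: ReadPair, scheme: BarcodeScheme, max_mismatch: int = 1
) -> DemuxAssignment:
    """Assign one read pair to a well, trying both mate orientations.

    The orientation with the lower total barcode mismatch count wins; an
    exact tie between two valid orientations is treated as ambiguous and
    the pair is left unassigned.  On success the spacer + barcode + linker
    prefix is trimmed from both mates.
    """
    candidates = []
    reasons = []
    for orientation, row_seq, col_seq in (
        (Orientation.ROW_FIRST, pair.seq1, pair.seq2),
        (Orientation.COLUMN_FIRST, pair.seq2, pair.seq1),
    ):
        row = assign_barcode(row_seq, Group.ROW, scheme, max_mismatch)
        col = assign_barcode(col_seq, Group.COLUMN, scheme, max_mismatch)
        reasons.extend([row.reason, col.reason])
        if row.primer_id is not None and col.primer_id is not None:
            candidates.append((row.mismatches + col.mismatches, orientation, row, col))

    if not candidates:
        if FailReason.AMBIGUOUS_BARCODE in reasons:
            reason = FailReason.AMBIGUOUS_BARCODE
        elif FailReason.TOO_MANY_MISMATCHES in reasons:
            reason = FailReason.TOO_MANY_MISMATCHES
        else:
            reason = FailReason.NO_SPACER
        return DemuxAssignment(pair.id, None, Orientation.NONE, (0, 0), None, reason)

    candidates.sort(key=lambda c: c[0])
    if len(candidates) == 2 and candidates[0][0] == candidates[1][0]:
        return DemuxAssignment(
            pair.id, None, Orientation.NONE, (0, 0), None, FailReason.AMBIGUOUS_BARCODE
        )
    _, orientation, row, col = candidates[0]
    well = scheme.well_for(row.primer_id, col.primer_id)
    trimmed = _trim(pair, row_on_mate1=(orientation is Orientation.ROW_FIRST), scheme=scheme)
    return DemuxAssignment(
        pair.id,
        well,
        orientation,
        (row.mismatches, col.mismatches),
        trimmed,
        FailReason.NONE,
    )


# ---------------------------------------------------------------------------
# whole-run demultiplexing


@dataclass
class DemuxResult:
    """Per-well trimmed read collections plus bookkeeping counts."""

    by_well: dict[str, list[ReadPair]] = field(default_factory=dict)
    unassigned: int = 0
    fail_reasons: Counter = field(default_factory=Counter)
    total: int = 0

    @property
    def assigned(self) -> int:
        return sum(len(v) for v in self.by_well.values())

    def counts_table(self):
        """TSV-ready per-well counts: well, assigned, fraction of total."""
        import pandas as pd

        rows = [
            {
                "well": label,
                "assigned": len(pairs),
                "fraction": len(pairs) / self.total if self.total else 0.0,
            }
            for label, pairs in sorted(self.by_well.items())
        ]
        return pd.DataFrame(rows, columns=["well", "assigned", "fraction"])


def demultiplex_run(
    pairs: Iterable[ReadPair],
    scheme: BarcodeScheme,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Demultiplex a stream of read pairs into per-well collections.

    Conservation holds exactly: assigned + unassigned == total input pairs.
    """
    result = DemuxResult()
    for pair in pairs:
        result.total += 1
        assignment = demultiplex_pair(pair, scheme, max_mismatch)
        if assignment.assigned:
            result.by_well.setdefault(assignment.well.label, []).append(
                assignment.trimmed_pair
            )
        else:
            result.unassigned += 1
            result.fail_reasons[assignment.fail_reason.value] += 1
    return result


def write_well_fastqs(result: DemuxResult, out_dir: str | Path, compress: bool = False) -> None:
    """Write one interleaved FASTQ per well, named by well label."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, pairs in sorted(result.by_well.items()):
        suffix = ".fastq.gz" if compress else ".fastq"
        path = out_dir / f"{label}{suffix}"
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            for p in pairs:
                fh.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
                fh.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")
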