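"""Plate report rendering: per-well text alignments and machine TSVs.

The per-allele view is a fixed-width, three-track text alignment —
reference, match track, allele — with regions of interest marked above
the reference and deletions shown as ``-`` in the allele row.  Inserted
bases do not consume reference columns; they are listed on a separate
``ins`` annotation line (``pos+SEQ``) under each block so reference
coordinates stay aligned.  The rendering is lossless: substitutions,
deletions and insertions can all be re-parsed from the block.

File outputs are deterministic: identical inputs produce byte-identical
TSV and text reports.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import TargetLocus, Variant
from .genotype import AlleleCount, PlateSummary, WellGenotype, WellStatus

__all__ = [
    "PlateReport",
    "render_well_alignment",
    "write_report",
    "parse_rendered_block",
]

DEFAULT_WIDTH = 60


@dataclass
class PlateReport:
    metadata: dict
    wells: list[WellGenotype]
    summary: PlateSummary
    locus: TargetLocus


def _tracks_for(allele: AlleleCount, locus: TargetLocus):
    """Build full-length (reference-coordinate) tracks plus insertions."""
    ref = locus.reference_amplicon
    aln = allele.alignment
    ref_track = list(ref)
    match_track = [" "] * len(ref)
    allele_track = [" "] * len(ref)  # leading/trailing blanks = not covered
    insertions: list[tuple[int, str]] = []

    i = aln.ref_start
    j = 0
    q = aln.query
    for op, n in aln.operations:
        if op in ("match", "mismatch"):
            for k in range(n):
                allele_track[i + k] = q[j + k]
                match_track[i + k] = "|" if op == "match" else " "
            i += n
            j += n
        elif op == "deletion":
            for k in range(n):
                allele_track[i + k] = "-"
            i += n
        else:  # insertion
            insertions.append((i, q[j : j + n]))
            j += n
    return ref_track, match_track, allele_track, insertions


def _roi_track(locus: TargetLocus) -> list[str]:
    track = [" "] * len(locus.reference_amplicon)
    for label, s, e in locus.regions_of_interest:
        for k in range(s, e):
            track[k] = "*"
        # inline the label where it fits
        text = label[: e - s]
        for k, ch in enumerate(text):
            track[s + k] = ch
    return track


def render_well_alignment(
    allele: AlleleCount, locus: TargetLocus, width: int = DEFAULT_WIDTH
) -> str:
    """Fixed-width text alignment of one allele against the reference."""
    ref_track, match_track, allele_track, insertions = _tracks_for(allele, locus)
    roi = _roi_track(locus)
    n = len(ref_track)
    lines = []
    for block in range(0, n, width):
        hi = min(block + width, n)
        lines.append(f"pos     {block}")
        if any(c != " " for c in roi[block:hi]):
            lines.append("roi     " + "".join(roi[block:hi]))
        lines.append("ref     " + "".join(ref_track[block:hi]))
        lines.append("        " + "".join(match_track[block:hi]))
        lines.append("allele  " + "".join(allele_track[block:hi]))
        block_ins = [(p, s) for p, s in insertions if block <= p < hi]
        if block_ins:
            lines.append("ins     " + " ".join(f"{p}+{s}" for p, s in block_ins))
        lines.append("")
    return "\n".join(lines)


def parse_rendered_block(text: str, locus: TargetLocus) -> list[Variant]:
    """Recover the variant list from a rendered alignment block.

    Used as the losslessness check on rendering; returns variants in the
    same left-aligned convention as the aligner (indels are re-normalised
    via the shared helper).
    """
    from .align import left_align

    ref = locus.reference_amplicon
    allele_track = [" "] * len(ref)
    insertions: list[tuple[int, str]] = []
    offset = 0
    for line in text.splitlines():
        if line.startswith("pos     "):
            offset = int(line.split()[1])
        elif line.startswith("allele  "):
            chunk = line[8:]
            for k, ch in enumerate(chunk):
                allele_track[offset + k] = ch
        elif line.startswith("ins     "):
            for item in line[8:].split():
                p, s = item.split("+")
                insertions.append((int(p), s))
    variants: list[Variant] = []
    i = 0
    n = len(ref)
    while i < n:
        ch = allele_track[i]
        if ch == "-":
            j = i
            while j < n and allele_track[j] == "-":
                j += 1
            variants.append(left_align(Variant(i, "deletion", ref[i:j], ""), ref))
            i = j
        else:
            if ch not in (" ", ref[i]):
                variants.append(Variant(i, "substitution", ref[i], ch))
            i += 1
    for p, s in insertions:
        variants.append(left_align(Variant(p, "insertion", "", s), ref))
    variants.sort(key=lambda v: (v.amplicon_position, v.kind))
    return variants


# ---------------------------------------------------------------------------
# file outputs


def _variant_notation(variants: Sequence[Variant]) -> str:
    return ";".join(v.notation() for v in variants) if variants else "."


def wells_frame(wells: Sequence[WellGenotype]) -> pd.DataFrame:
    rows = []
    for w in wells:
        rows.append(
            {
                "well": w.well.label if w.well else ".",
                "status": w.status.value,
                "total_reads": w.total_merged_reads,
                "genotype": w.genotype_string or ".",
                "homozygote_flag": int(w.homozygote_flag),
                "n_called_alleles": len(w.called_alleles),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["well", "status", "total_reads", "genotype", "homozygote_flag", "n_called_alleles"],
    )


def alleles_frame(wells: Sequence[WellGenotype]) -> pd.DataFrame:
    rows = []
    for w in wells:
        for rank, a in enumerate(w.all_alleles, 1):
            rows.append(
                {
                    "well": w.well.label if w.well else ".",
                    "rank": rank,
                    "count": a.count,
                    "fraction": round(a.fraction, 6),
                    "class": a.allele_class.value,
                    "called": int(a in w.called_alleles),
                    "variants": _variant_notation(a.variants),
                }
            )
    return pd.DataFrame(
        rows, columns=["well", "rank", "count", "fraction", "class", "called", "variants"]
    )


def summary_frame(summary: PlateSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "wells_processed": summary.wells_processed,
                "successfully_sequenced": summary.wells_sequenced,
                "success_rate": f"{summary.success_rate:.1f}%",
            }
        ]
    )


def _report_text(report: PlateReport, max_rendered_alleles: int = 4) -> str:
    lines = ["# ampliplate plate report", ""]
    lines.append("## Run metadata")
    for key, value in report.metadata.items():
        lines.append(f"{key}: {value}")
    locus = report.locus
    lines.append(f"locus: {locus.name} {locus.chrom}:{locus.start}-{locus.end}")
    lines.append(f"reference_amplicon: {locus.reference_amplicon}")
    for label, s, e in locus.regions_of_interest:
        lines.append(f"region_of_interest: {label} [{s},{e})")
    if locus.donor_diffs:
        for pos, ref, alt in locus.donor_diffs:
            lines.append(f"donor_substitution: {pos}:{ref}>{alt}")
    lines.append("")
    lines.append("## Plate summary")
    s = report.summary
    lines.append("wells_processed\tsuccessfully_sequenced\tsuccess_rate")
    lines.append(f"{s.wells_processed}\t{s.wells_sequenced}\t{s.success_rate:.1f}%")
    lines.append("")
    lines.append("## Wells")
    for w in report.wells:
        label = w.well.label if w.well else "."
        lines.append("")
        lines.append(f"### Well {label}  [{w.status.value}]  reads={w.total_merged_reads}")
        if w.status is WellStatus.REPORTED:
            flag = "  (homozygous call - verify against large-deletion artefacts)" if w.homozygote_flag else ""
            lines.append(f"genotype: {w.genotype_string}{flag}")
            for rank, a in enumerate(w.called_alleles[:max_rendered_alleles], 1):
                lines.append(
                    f"allele {rank}: count={a.count} fraction={a.fraction:.3f} "
                    f"class={a.allele_class.value} variants={_variant_notation(a.variants)}"
                )
                lines.append(render_well_alignment(a, report.locus))
    lines.append("")
    return "\n".join(lines)


def write_report(
    report: PlateReport, out_dir: str | Path, formats: set[str] = frozenset({"txt", "tsv"})
) -> dict[str, Path]:
    """Write wells.tsv, alleles.tsv, summary.tsv and report.txt (+ html).

    TSVs are always written; 'txt' adds the human-readable report and
    'html' an HTML rendering of the same content.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frames = {
        "wells": wells_frame(report.wells),
        "alleles": alleles_frame(report.wells),
        "summary": summary_frame(report.summary),
    }
    for name, frame in frames.items():
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        paths[name] = path

    if "txt" in formats:
        text = _report_text(report)
        path = out / "report.txt"
        path.write_text(text)
        paths["report"] = path
    if "html" in formats:
        body = _html.escape(_report_text(report))
        path = out / "report.html"
        path.write_text(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>ampliplate report</title></head>"
            f"<body><pre>{body}</pre></body></html>"
        )
        paths["html"] = path
    return paths
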