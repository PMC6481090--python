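"""End-to-end pipeline: demultiplex -> merge -> align -> genotype -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .align import Scoring
from .demux import demultiplex_run, load_scheme
from .genotype import (
    WellGenotype,
    call_genotype,
    collapse_alleles,
    summarize_plate,
)
from .io import RunConfig, load_locus, read_fastq_list, read_fastq_pairs
from .merge import MergedFragment, merge_pair
from .report import PlateReport, write_report

__all__ = ["run_pipeline"]

log = logging.getLogger("ampliplate")


def run_pipeline(config: RunConfig) -> PlateReport:
    """Run the full analysis described by ``config`` and write all outputs.

    Per-stage read accounting is logged to stderr and written to a
    machine-readable manifest; every input pair ends up in exactly one of
    assigned-and-merged, assigned-unmerged, or unassigned.
    """
    config.validate()
    scheme = load_scheme(config.fwd_primers, config.rev_primers)
    locus = load_locus(config.bed, config.reference, config.donor)
    scoring = Scoring(config.match, config.mismatch, config.gap_open, config.gap_extend)

    demux_total = 0
    merged_by_well: dict[str, list[MergedFragment]] = {}
    merge_failed = 0
    unassigned = 0
    for fastq1, fastq2 in read_fastq_list(config.fastq_list):
        log.info("demultiplexing %s / %s", fastq1, fastq2)
        result = demultiplex_run(
            read_fastq_pairs(fastq1, fastq2), scheme, config.max_mismatch
        )
        demux_total += result.total
        unassigned += result.unassigned
        for label, pairs in result.by_well.items():
            bucket = merged_by_well.setdefault(label, [])
            for pair in pairs:
                merged = merge_pair(pair, config.min_overlap, config.max_mismatch_ratio)
                if isinstance(merged, MergedFragment):
                    bucket.append(merged)
                else:
                    merge_failed += 1
    assigned_merged = sum(len(v) for v in merged_by_well.values())
    log.info(
        "demux: %d pairs total, %d assigned+merged, %d assigned but unmerged, %d unassigned",
        demux_total,
        assigned_merged,
        merge_failed,
        unassigned,
    )

    wells: list[WellGenotype] = []
    for label in sorted(merged_by_well):
        fragments = merged_by_well[label]
        alleles = collapse_alleles(fragments, locus, scoring)
        wells.append(
            call_genotype(
                alleles,
                ploidy=config.ploidy,
                min_reads=config.min_reads,
                min_allele_fraction=config.min_allele_fraction,
                well=scheme.address_of(label),
            )
        )
    summary = summarize_plate(wells)
    log.info(
        "genotyping: %d wells processed, %d reported (%.1f%%)",
        summary.wells_processed,
        summary.wells_sequenced,
        summary.success_rate,
    )

    metadata = {
        "fastq_list": str(config.fastq_list),
        "fwd_primers": str(config.fwd_primers),
        "rev_primers": str(config.rev_primers),
        "spacer": scheme.spacer,
        "row_linker": scheme.row_linker,
        "column_linker": scheme.column_linker,
        "barcode_length": scheme.barcode_length,
        **{f"param_{k}": v for k, v in config.parameters().items()},
    }
    report = PlateReport(metadata=metadata, wells=wells, summary=summary, locus=locus)

    formats = {"txt", "tsv"} | ({"html"} if config.write_html else set())
    out_paths = write_report(report, config.out_dir, formats)
    manifest = {
        "parameters": config.parameters(),
        "counts": {
            "input_pairs": demux_total,
            "unassigned": unassigned,
            "assigned_merged": assigned_merged,
            "assigned_unmerged": merge_failed,
            "wells_processed": summary.wells_processed,
            "wells_sequenced": summary.wells_sequenced,
        },
        "success_rate": summary.success_rate,
        "outputs": {k: str(v) for k, v in out_paths.items()},
    }
    manifest_path = Path(config.out_dir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
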