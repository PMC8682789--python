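"""End-to-end orchestration: detect -> re-align -> classify -> cluster ->
merge -> filter -> report."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .candidates import (
    FilterConfig,
    ProphageCandidate,
    cluster_evidence,
    filter_candidates,
    merge_discordant,
    render_report,
)
from .contigs import CrossContigCandidate, detect_cross_contig_candidates
from .detect import ClipBounds, scan_alignments
from .realign import RealignConfig, verify_candidates
from .sam_io import AlignmentRecord, read_alignments, read_fasta

__all__ = ["TraceResult", "run_trace", "run_trace_records"]


@dataclass(slots=True)
class TraceResult:
    candidates: list[ProphageCandidate]
    cross_candidates: list[CrossContigCandidate]
    stage_counts: dict[str, int]
    evidence: list = field(default_factory=list)


def run_trace_records(
    records: Iterable[AlignmentRecord],
    reference: dict[str, str],
    mode: Literal["chromosome", "contig", "auto"] = "chromosome",
    filter_config: FilterConfig = FilterConfig(),
    realign_config: RealignConfig | None = None,
    bounds: ClipBounds = ClipBounds(),
    lenient_flags: bool = False,
    drop_duplicates: bool = False,
) -> TraceResult:
    """Run the full pipeline over an alignment stream.

    ``mode="auto"`` switches to contig rules when the reference holds
    more than one sequence.  Zero candidates is a valid outcome.
    """
    if mode == "auto":
        mode = "contig" if len(reference) > 1 else "chromosome"
    if realign_config is None:
        realign_config = RealignConfig(search_reverse=(mode == "contig"))

    scan = scan_alignments(
        records, mode=mode, bounds=bounds,
        lenient_flags=lenient_flags, drop_duplicates=drop_duplicates,
    )
    for cand in scan.splits:
        if cand.record.is_mapped and cand.record.ref_name not in reference:
            raise KeyError(
                f"alignment references sequence {cand.record.ref_name!r} "
                f"absent from the reference FASTA"
            )
    evidence, cross_pairs, dropped = verify_candidates(
        scan.splits, reference, realign_config
    )
    clusters = cluster_evidence(evidence, tol=filter_config.cluster_tol)
    clusters, drp_dropped = merge_discordant(
        clusters, scan.discordants, window=filter_config.drp_window
    )
    candidates = filter_candidates(clusters, filter_config)
    cross = (
        detect_cross_contig_candidates(cross_pairs, scan.discordants, reference, filter_config)
        if mode == "contig"
        else []
    )
    counts = {
        "records_scanned": scan.n_records,
        "split_candidates": len(scan.splits),
        "discordant_candidates": len(scan.discordants),
        "verified_junctions": len(evidence),
        "cross_contig_junctions": len(cross_pairs),
        "unverified": dropped["unverified"],
        "unclassifiable": dropped["unclassifiable"],
        "clusters": len(clusters),
        "drp_unassigned": drp_dropped,
        "candidates": len(candidates),
        "cross_contig_candidates": len(cross),
    }
    return TraceResult(candidates, cross, counts, evidence)


def run_trace(
    sam_path: str,
    fasta_path: str,
    outdir: str | None = None,
    **kwargs,
) -> TraceResult:
    """File-level wrapper: read SAM/BAM + FASTA, run, optionally write
    the TSV report, evidence text and stage-count JSON."""
    reference = read_fasta(fasta_path)
    result = run_trace_records(read_alignments(sam_path), reference, **kwargs)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: TraceResult, outdir: str) -> None:
    import json

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    render_report(result.candidates).to_csv(
        os.path.join(outdir, "prophages.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "evidence.txt"), "w") as fh:
        for c in result.candidates:
            fh.write(f"# {c.name} {c.ref_name}:{c.attL_start}-{c.attR_end}\n")
            fh.write(c.evidence_alignments + "\n")
    if result.cross_candidates:
        rows = [
            {
                "prophage": c.name,
                "contig_a": c.contig_a,
                "attL_start_a": c.attL_start,
                "attL_end_a": c.attL_end,
                "contig_b": c.contig_b,
                "attR_start_b": c.attR_start,
                "attR_end_b": c.attR_end,
                "orientation": c.orientation,
                "approx_size": c.approx_size,
                "att_length": c.att_len,
                "SR_attB": c.sr_attB,
                "SR_attP": c.sr_attP,
                "SR_ambiguous": c.sr_ambiguous,
                "DRP_attB": c.drp_attB,
                "DRP_attP": c.drp_attP,
                "junction_annotation": c.junction_annotation,
            }
            for c in result.cross_candidates
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "prophages_cross_contig.tsv"), sep="\t", index=False
        )
    with open(os.path.join(outdir, "run_summary.json"), "w") as fh:
        json.dump(result.stage_counts, fh, indent=2)
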