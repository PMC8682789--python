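"""Benchmark protocols: detection limits of the junction caller on
simulated read mixtures.

These routines reproduce the simulation experiments used to
characterise the method: the att-length ceiling of split-read recovery,
the minimum sequencing depth at which rare excision events leave
detectable junction evidence, end-to-end parameter recovery, and the
chromosome-level vs contig-level equivalence.  All randomness derives
from a single base seed through named child streams, so every
experiment is reproducible.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .detect import scan_alignments
from .pipeline import run_trace_records
from .realign import verify_candidates
from .simulate import (
    SimParams,
    evaluate_calls,
    simulate_prophage_genome,
    simulate_read_mixture,
    split_reference,
)

__all__ = [
    "count_verified_junctions",
    "att_length_ceiling",
    "min_depth_for_detection",
    "parameter_recovery",
    "contig_equivalence",
]


def _child_seed(base_seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and a key."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def count_verified_junctions(params: SimParams) -> int:
    """Simulate one library and run extraction + overlap verification,
    returning the number of verified junction-supporting split reads."""
    truth = simulate_prophage_genome(params)
    _, records = simulate_read_mixture(truth)
    scan = scan_alignments(iter(records))
    evidence, _, _ = verify_candidates(scan.splits, {"chr": truth.wt_seq})
    return len(evidence)


def att_length_ceiling(
    att_grid: Sequence[int] = (2,) + tuple(range(10, 161, 10)),
    host_len: int = 200_000,
    prophage_size: int = 20_000,
    depth: float = 100.0,
    ratios: tuple[float, float, float] = (97.0, 2.0, 1.0),
    seeds_per_length: int = 3,
    base_seed: int = 0,
) -> dict:
    """Largest att core length at which at least one junction-supporting
    split read is verified, over a sweep of att lengths.

    With 2x150 bp reads and 10 bp minimum flanks the geometric ceiling
    is read_len - 2*10 = 130 bp: a junction read must carry the whole
    core plus both flanks.
    """
    per_length = {}
    ceiling = 0
    for a in att_grid:
        n = 0
        for s in range(seeds_per_length):
            p = SimParams(
                genome_len=host_len, att_len=int(a), prophage_size=prophage_size,
                ratios=ratios, depth=depth, error_rate=0.0,
                seed=_child_seed(base_seed, 3, a, s),
            )
            n += count_verified_junctions(p)
        per_length[int(a)] = n
        if n > 0:
            ceiling = int(a)
    return {"ceiling": ceiling, "per_length": per_length}


def min_depth_for_detection(
    ratios: tuple[float, float, float],
    depths: Sequence[float] = (10, 20, 50, 100),
    replicates: int = 20,
    host_len: int = 400_000,
    prophage_size: int = 20_000,
    att_len: int = 20,
    base_seed: int = 0,
) -> dict:
    """Smallest depth (ascending scan, stopping at the first success) at
    which at least one replicate genome yields verified junction
    evidence.  Event-count filtering is irrelevant here: a single
    verified read counts as evidence."""
    tried = {}
    for depth in sorted(depths):
        hits = 0
        for r in range(replicates):
            p = SimParams(
                genome_len=host_len, att_len=att_len, prophage_size=prophage_size,
                ratios=ratios, depth=float(depth),
                seed=_child_seed(base_seed, 4, int(depth), r, *[int(x) for x in ratios]),
            )
            if count_verified_junctions(p) > 0:
                hits += 1
        tried[float(depth)] = hits
        if hits > 0:
            return {"min_depth": float(depth), "replicate_hits": tried}
    return {"min_depth": float("nan"), "replicate_hits": tried}


def parameter_recovery(
    n_draws: int = 10,
    host_len: int = 150_000,
    depth: float = 100.0,
    ratios: tuple[float, float, float] = (97.0, 2.0, 1.0),
    base_seed: int = 0,
) -> dict:
    """End-to-end recovery of the true att quad over random genome
    draws, plus excision-free negative controls.

    att lengths are drawn from the detectable range (2-130 bp, the
    geometric ceiling of 150 bp reads with 10 bp flanks) and prophage
    sizes from 5-50 kb so they fit the scaled host; error-free reads.
    Recovery requires the full default pipeline (both evidence classes,
    all filters) to report the exact four endpoints.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 5]))
    exact = 0
    hits = 0
    negative_calls = 0
    draws = []
    for i in range(n_draws):
        att = int(rng.integers(2, 131))
        size = int(rng.integers(5_000, 50_001))
        seed = _child_seed(base_seed, 5, i)
        p = SimParams(
            genome_len=host_len, att_len=att, prophage_size=size,
            ratios=ratios, depth=depth, error_rate=0.0, seed=seed,
        )
        truth = simulate_prophage_genome(p)
        _, records = simulate_read_mixture(truth)
        res = run_trace_records(iter(records), {"chr": truth.wt_seq})
        report = evaluate_calls(truth, res.candidates, tol=2)
        exact += bool(report["exact"])
        hits += bool(report["hit"])
        draws.append({"att_len": att, "prophage_size": size,
                      "exact": bool(report["exact"]),
                      "n_candidates": len(res.candidates)})
        # negative control: same genome, excision-free mixture
        neg = replace(p, ratios=(1.0, 0.0, 0.0))
        neg_truth = simulate_prophage_genome(neg)
        _, neg_records = simulate_read_mixture(neg_truth)
        neg_res = run_trace_records(iter(neg_records), {"chr": neg_truth.wt_seq})
        negative_calls += len(neg_res.candidates)
    return {"n_draws": n_draws, "exact": exact, "hits": hits,
            "negative_calls": negative_calls, "draws": draws}


def contig_equivalence(base_seed: int = 0) -> dict:
    """Split one simulated chromosome inside the prophage into two
    contigs and compare the contig-mode call with the chromosome-mode
    call after offset mapping."""
    p = SimParams(
        genome_len=200_000, att_len=30, att_mismatches=0, prophage_size=20_000,
        ratios=(2.0, 1.0, 1.0), depth=60, error_rate=0.0,
        seed=_child_seed(base_seed, 6),
    )
    truth = simulate_prophage_genome(p)
    _, records = simulate_read_mixture(truth)
    chrom = run_trace_records(iter(records), {"chr": truth.wt_seq}, mode="chromosome")
    if len(chrom.candidates) != 1:
        return {"equivalent": False, "reason": "chromosome-mode call missing"}
    cc = chrom.candidates[0]

    brk = (truth.truth_quad.attL_end + truth.truth_quad.attR_start) // 2
    ref2, layout = split_reference(truth, brk)
    _, records2 = simulate_read_mixture(truth, layout=layout)
    contig = run_trace_records(iter(records2), ref2, mode="contig")
    if len(contig.cross_candidates) != 1:
        return {"equivalent": False, "reason": "cross-contig call missing"}
    xc = contig.cross_candidates[0]
    mapped = (xc.attL_start, xc.attL_end, xc.attR_start + brk, xc.attR_end + brk)
    chrom_pts = (cc.attL_start, cc.attL_end, cc.attR_start, cc.attR_end)
    return {
        "equivalent": mapped == chrom_pts and xc.approx_size == cc.size,
        "chromosome_call": chrom_pts,
        "contig_call_mapped": mapped,
        "approx_size": xc.approx_size,
        "size": cc.size,
    }
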