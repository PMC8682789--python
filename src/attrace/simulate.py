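"""Synthetic prophage genomes and paired-end read mixtures with truth
alignments.

The generator reproduces the three-molecule design used to benchmark
junction detection: a host genome carrying one integrated prophage
(attL...prophage...attR, the two att copies sharing a common core with
optional 1-2 bp mismatches), the same host after excision (a single attB
core), and the circularised phage (a single attP core).  Paired 2x150 bp
reads are drawn from the three molecules in proportion to molecule
copy-number ratio x molecule length until the wild-type genome reaches
the requested fold coverage.

Instead of running an aligner, each read's alignment back to the
wild-type reference is computed from its known provenance: reads
crossing the attB or attP junction are emitted as soft-clipped records
shaped exactly as a BWA-style aligner would shape them (primary
alignment on the longer piece, the shorter flank soft-clipped, FLAG bits
assembled from the pair geometry), and all other reads as plain linear
records.  An optional contig layout re-expresses the truth alignments
against a fragmented draft assembly of the same genome.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .candidates import ProphageCandidate
from .realign import AttQuad, revcomp
from .sam_io import (
    AlignmentRecord,
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    FLAG_SECOND,
    write_sam,
)

__all__ = [
    "SimParams",
    "GenomeTruth",
    "SimulatedReadPair",
    "ContigPiece",
    "simulate_prophage_genome",
    "simulate_read_mixture",
    "split_reference",
    "evaluate_calls",
    "sensitivity",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationParameterError(ValueError):
    pass


@dataclass(slots=True, frozen=True)
class SimParams:
    """Study conditions for one simulated genome + library.

    ``None`` for ``gc``, ``att_len``, ``att_mismatches`` or
    ``prophage_size`` means "draw from the benchmark range" (GC 0.20-0.80,
    att core 2-145 bp, 1-2 mismatches between the att copies when the
    core exceeds 2 bp, prophage 5000-150000 bp).  Ratios are molecule
    copy numbers WT : excised-host (attB) : circular phage (attP); the
    read share of each molecule is ratio x molecule length.  Depth is
    fold coverage of the wild-type genome.
    """

    genome_len: int = 4_000_000
    gc: float | None = None
    att_len: int | None = None
    att_mismatches: int | None = None
    prophage_size: int | None = None
    ratios: tuple[float, float, float] = (1000.0, 1.0, 1.0)
    depth: float = 100.0
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.genome_len < 20_000:
            raise SimulationParameterError("genome_len too small to host a prophage")
        if self.gc is not None and not 0.20 <= self.gc <= 0.80:
            raise SimulationParameterError("gc outside [0.20, 0.80]")
        if self.att_len is not None and not 2 <= self.att_len <= 200:
            raise SimulationParameterError("att_len outside [2, 200]")
        if self.prophage_size is not None and not 5_000 <= self.prophage_size <= 150_000:
            raise SimulationParameterError("prophage_size outside [5000, 150000]")
        if (
            self.prophage_size is not None
            and self.prophage_size >= self.genome_len - 4 * _MARGIN
        ):
            raise SimulationParameterError("prophage_size too large for genome_len")
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios) or not any(self.ratios):
            raise SimulationParameterError("ratios must be three nonnegative values, not all zero")
        if self.depth <= 0:
            raise SimulationParameterError("depth must be positive")
        if self.read_len < 30:
            raise SimulationParameterError("read_len too short")
        if not 0 <= self.error_rate < 0.2:
            raise SimulationParameterError("error_rate outside [0, 0.2)")


_MARGIN = 2_000  # host flank kept free of the prophage on either side


@dataclass(slots=True)
class GenomeTruth:
    """One simulated genome triplet with its known att geometry."""

    wt_seq: str
    excised_seq: str
    circular_seq: str
    truth_quad: AttQuad
    att_core: str       # the attL/attB copy
    att_core_alt: str   # the attR/attP copy (with the simulated mismatches)
    params: SimParams   # with all draws resolved


@dataclass(slots=True)
class SimulatedReadPair:
    source: Literal["WT", "attB", "attP"]
    frag_start: int     # 1-based on the source molecule
    frag_len: int
    seq1: str           # sequenced orientation of the first-in-pair mate
    seq2: str
    crosses_junction: bool


@dataclass(slots=True, frozen=True)
class ContigPiece:
    """One contig of a derived draft assembly: a slice of the wild-type
    genome, optionally in reverse orientation."""

    name: str
    wt_start: int  # 1-based inclusive
    wt_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.wt_end - self.wt_start + 1


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=min(n_sub, len(arr)), replace=False)
    for i in pos:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def resolve_params(p: SimParams) -> SimParams:
    """Draw any unset parameters from the benchmark ranges (deterministic
    given the seed; the draws consume a dedicated RNG stream)."""
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0xA77]))
    gc = p.gc if p.gc is not None else float(np.round(rng.uniform(0.20, 0.80), 3))
    att = p.att_len if p.att_len is not None else int(rng.integers(2, 146))
    if p.att_mismatches is not None:
        mm = p.att_mismatches
    else:
        mm = int(rng.integers(1, 3)) if att > 2 else 0
    if att <= 2:
        mm = 0
    size_hi = min(150_000, p.genome_len - 4 * _MARGIN - 1)
    size = p.prophage_size if p.prophage_size is not None else int(rng.integers(5_000, size_hi + 1))
    return replace(p, gc=gc, att_len=att, att_mismatches=mm, prophage_size=size)


def simulate_prophage_genome(p: SimParams) -> GenomeTruth:
    """Build the WT / excised / circular molecule triplet.

    The prophage cassette (attL core + interior + attR core) is inserted
    at a uniform random position of a random-composition host backbone;
    the attR copy carries the requested number of substitutions relative
    to attL when the core exceeds 2 bp.
    """
    p = resolve_params(p)
    rng = np.random.default_rng(p.seed)
    a = p.att_len
    size = p.prophage_size
    if size <= a + 1:
        raise SimulationParameterError("prophage_size must exceed att_len + 1")
    backbone_len = p.genome_len - size - a
    if backbone_len < 2 * _MARGIN + 1:
        raise SimulationParameterError("genome_len leaves no host backbone")

    backbone = _random_dna(rng, backbone_len, p.gc)
    interior = _random_dna(rng, size - a, p.gc)
    core = _random_dna(rng, a, p.gc)
    core_alt = _mutate(rng, core, p.att_mismatches)

    u_len = int(rng.integers(_MARGIN, backbone_len - _MARGIN + 1))
    u, d = backbone[:u_len], backbone[u_len:]

    # keep the att core maximal: if the base after attL equalled the
    # base after attR (or before attR equalled before attL) the genome
    # would carry a longer direct repeat than the declared core
    if interior[0] == d[0]:
        interior = _other_base(rng, d[0]) + interior[1:]
    if interior[-1] == u[-1]:
        interior = interior[:-1] + _other_base(rng, u[-1])

    wt = u + core + interior + core_alt + d
    excised = u + core + d
    circular = core_alt + interior

    quad = AttQuad(
        ref_name="chr",
        attL_start=u_len + 1,
        attL_end=u_len + a,
        attR_start=u_len + 1 + size,
        attR_end=u_len + size + a,
    )
    assert len(wt) == len(excised) + quad.size
    assert len(circular) == quad.size
    return GenomeTruth(wt, excised, circular, quad, core, core_alt, p)


# ---------------------------------------------------------------------------
# truth-alignment geometry


def _map_excised(s: int, e: int, u_len: int, a: int, size: int):
    """Map a 1-based excised-molecule interval [s, e] to wild-type
    segments (wt_start, wt_end, q_start, q_end).  Reads extending across
    the attB junction with flank on both sides split into two pieces
    whose query intervals overlap by the att core length."""
    j = u_len + a  # last excised position mapping to attL_end
    if e <= j:
        return [(s, e, 1, e - s + 1)]
    if s >= u_len + 1:
        return [(s + size, e + size, 1, e - s + 1)]
    return [
        (s, j, 1, j - s + 1),
        (u_len + 1 + size, e + size, u_len + 1 - s + 1, e - s + 1),
    ]


def _map_circle(s: int, e: int, u_len: int, a: int, size: int):
    """Map a 1-based circular-molecule interval to wild-type segments.

    The circle is the string attP-core + interior, indexed modulo its
    length; ``s`` is normalised to [1, size] and ``e`` may run into the
    second period.  Only reads covering the whole core with interior on
    both sides are true attP junction reads; every other placement has a
    linear image on the wild type (through the attR copy, or through the
    attL copy when the read runs from the core into the interior)."""
    attL_start = u_len + 1
    attL_end = u_len + a
    attR_start = u_len + 1 + size
    if e <= size:
        if s > a:  # pure interior
            return [(attL_end + s - a, attL_end + e - a, 1, e - s + 1)]
        if e <= a:  # inside the core
            return [(attR_start + s - 1, attR_start + e - 1, 1, e - s + 1)]
        # core into interior: linear through the attL copy
        return [(attL_start + s - 1, attL_end + (e - a), 1, e - s + 1)]
    e2 = e - size
    if e2 <= a:
        # interior suffix into the core: linear through the attR copy
        return [(attL_end + s - a, attR_start + e2 - 1, 1, e - s + 1)]
    # full core with interior on both sides: the attP junction read
    attR_end = attR_start + a - 1
    return [
        (attL_end + s - a, attR_end, 1, size + a - s + 1),
        (attL_start, attL_end + (e2 - a), size + 1 - s + 1, e - s + 1),
    ]


def _project_segments(segs, layout: Sequence[ContigPiece] | None, read_len: int):
    """Re-express wild-type segments on a contig layout.  Segments
    crossing a contig boundary are cut; pieces on '-' contigs get
    mirrored contig coordinates and a '-' segment strand."""
    if layout is None:
        return [("chr", r0, r1, q0, q1, "+") for r0, r1, q0, q1 in segs]
    out = []
    for r0, r1, q0, q1 in segs:
        for piece in layout:
            lo, hi = max(r0, piece.wt_start), min(r1, piece.wt_end)
            if lo > hi:
                continue
            qa = q0 + (lo - r0)
            qb = q0 + (hi - r0)
            if piece.strand == "+":
                c0 = lo - piece.wt_start + 1
                c1 = hi - piece.wt_start + 1
                out.append((piece.name, c0, c1, qa, qb, "+"))
            else:
                c0 = piece.wt_end - hi + 1
                c1 = piece.wt_end - lo + 1
                out.append((piece.name, c0, c1, qa, qb, "-"))
    return out


def _primary(segs):
    """BWA-style primary piece: the longest query span (ties towards the
    query prefix)."""
    return max(segs, key=lambda s: (s[4] - s[3] + 1, -s[3]))


# ---------------------------------------------------------------------------
# read mixture


def simulate_read_mixture(
    truth: GenomeTruth,
    params: SimParams | None = None,
    layout: Sequence[ContigPiece] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimulatedReadPair], list[AlignmentRecord]]:
    """Draw the paired-read mixture and its truth alignments.

    Returns the read pairs (sequenced orientation) and the truth SAM
    records against the wild-type genome (or against ``layout`` when a
    draft-assembly view is requested).  Deterministic given the params
    seed; an explicit ``rng`` overrides it for replicate series.
    """
    p = params or truth.params
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0x5EAD]))
    read_len = p.read_len
    u_len = truth.truth_quad.attL_start - 1
    a = truth.truth_quad.att_len
    size = truth.truth_quad.size

    molecules = (
        ("WT", truth.wt_seq, False),
        ("attB", truth.excised_seq, False),
        ("attP", truth.circular_seq, True),
    )
    lengths = np.array([len(m[1]) for m in molecules], dtype=float)
    weights = np.asarray(p.ratios, dtype=float) * lengths
    n_pairs = int(round(p.depth * len(truth.wt_seq) / (2 * read_len)))
    if n_pairs <= 0:
        raise SimulationParameterError("depth and genome length give zero read pairs")
    counts = rng.multinomial(n_pairs, weights / weights.sum())

    pairs: list[SimulatedReadPair] = []
    records: list[AlignmentRecord] = []
    pair_idx = 0
    for (source, mol, circular), n in zip(molecules, counts):
        if n == 0:
            continue
        mol_len = len(mol)
        frag_cap = min(1_000, mol_len)
        frag_lo = 2 * read_len
        if frag_cap < frag_lo:
            continue
        frags = np.clip(
            np.rint(rng.normal(p.insert_mean, p.insert_sd, size=n)), frag_lo, frag_cap
        ).astype(np.int64)
        if circular:
            starts = rng.integers(0, mol_len, size=n)
            mol2 = mol + mol[: frag_cap]
        else:
            starts = (rng.random(n) * (mol_len - frags + 1)).astype(np.int64)
            mol2 = mol
        swap_mate = rng.random(n) < 0.5
        n_err = (
            rng.poisson(p.error_rate * read_len, size=2 * n)
            if p.error_rate > 0
            else np.zeros(2 * n, dtype=np.int64)
        )
        for i in range(n):
            s0 = int(starts[i])
            frag = int(frags[i])
            fwd_seq = mol2[s0: s0 + read_len]
            rev_seq = mol2[s0 + frag - read_len: s0 + frag]
            if n_err[2 * i]:
                fwd_seq = _mutate(rng, fwd_seq, int(n_err[2 * i]))
            if n_err[2 * i + 1]:
                rev_seq = _mutate(rng, rev_seq, int(n_err[2 * i + 1]))
            fs, fe = s0 + 1, s0 + read_len
            rs, re_ = s0 + frag - read_len + 1, s0 + frag
            if source == "WT":
                fwd_segs = [(fs, fe, 1, read_len)]
                rev_segs = [(rs, re_, 1, read_len)]
                crosses = False
            elif source == "attB":
                fwd_segs = _map_excised(fs, fe, u_len, a, size)
                rev_segs = _map_excised(rs, re_, u_len, a, size)
                crosses = len(fwd_segs) > 1 or len(rev_segs) > 1
            else:
                s_norm = (fs - 1) % size + 1
                shift = fs - s_norm
                fwd_segs = _map_circle(s_norm, fe - shift, u_len, a, size)
                rs_n = (rs - 1) % size + 1
                rev_segs = _map_circle(rs_n, re_ - (rs - rs_n), u_len, a, size)
                crosses = len(fwd_segs) > 1 or len(rev_segs) > 1
            name = f"sim{pair_idx}"
            rec_f, rec_r = _assemble_pair(
                name, fwd_seq, rev_seq, fwd_segs, rev_segs,
                bool(swap_mate[i]), layout, read_len,
            )
            records.append(rec_f)
            records.append(rec_r)
            if swap_mate[i]:
                seq1, seq2 = revcomp(rev_seq), revcomp(fwd_seq)
            else:
                seq1, seq2 = fwd_seq, revcomp(rev_seq)
            pairs.append(SimulatedReadPair(source, s0 + 1, frag, seq1, seq2, crosses))
            pair_idx += 1
    return pairs, records


_PROPER_MAX_SPAN = 1_000


def _assemble_pair(name, fwd_seq, rev_seq, fwd_segs, rev_segs, swap_mate,
                   layout, read_len):
    f = _layout_record_parts(fwd_seq, fwd_segs, False, layout, read_len)
    r = _layout_record_parts(rev_seq, rev_segs, True, layout, read_len)

    # proper as an aligner would call it: same reference, FR orientation
    # with the forward read leftmost, plausible span
    proper = False
    if f["ref"] == r["ref"] and f["reverse"] != r["reverse"]:
        lead, trail = (f, r) if f["pos"] <= r["pos"] else (r, f)
        proper = (
            not lead["reverse"]
            and trail["reverse"]
            and (trail["end"] - lead["pos"] + 1) <= _PROPER_MAX_SPAN
        )

    def build(part, other, first):
        flag = FLAG_PAIRED
        if proper:
            flag |= FLAG_PROPER
        if part["reverse"]:
            flag |= FLAG_REVERSE
        if other["reverse"]:
            flag |= FLAG_MATE_REVERSE
        flag |= FLAG_FIRST if first else FLAG_SECOND
        if part["ref"] == other["ref"]:
            tlen = max(f["end"], r["end"]) - min(f["pos"], r["pos"]) + 1
            if part["pos"] > other["pos"] or (part["pos"] == other["pos"] and not first):
                tlen = -tlen
        else:
            tlen = 0
        return AlignmentRecord(
            query_name=name,
            flag_raw=flag,
            ref_name=part["ref"],
            pos=part["pos"],
            mapq=60,
            cigar=part["cigar"],
            mate_ref_name=other["ref"],
            mate_pos=other["pos"],
            tlen=tlen,
            query_seq=part["seq"],
            qual="I" * read_len,
        )

    rec_f = build(f, r, first=not swap_mate)
    rec_r = build(r, f, first=swap_mate)
    return rec_f, rec_r


def _layout_record_parts(seq, segs, is_reverse, layout, read_len):
    """Resolve one read's primary alignment on the output reference.

    ``seq`` is the reference-forward (wild-type forward) slice of the
    molecule.  When the primary piece lands on a '-' oriented contig the
    whole record flips: coordinates were already mirrored by the
    projection, and here the stored sequence and query interval flip to
    the contig's forward strand.
    """
    proj = _project_segments(segs, layout, read_len)
    c, r0, r1, q0, q1, strand = _primary(proj)
    flipped = strand == "-"
    if flipped:
        q0, q1 = read_len - q1 + 1, read_len - q0 + 1
        out_seq = revcomp(seq)
    else:
        out_seq = seq
    cigar = []
    if q0 > 1:
        cigar.append(("S", q0 - 1))
    cigar.append(("M", q1 - q0 + 1))
    if q1 < read_len:
        cigar.append(("S", read_len - q1))
    return {
        "ref": c,
        "pos": r0,
        "end": r1,
        "cigar": tuple(cigar),
        "seq": out_seq,
        "reverse": is_reverse ^ flipped,
    }


def split_reference(
    truth: GenomeTruth,
    break_at: int,
    names: tuple[str, str] = ("contig1", "contig2"),
    invert_second: bool = False,
) -> tuple[dict[str, str], list[ContigPiece]]:
    """Split the wild-type genome into a two-contig draft assembly at a
    1-based position (the second contig starts at ``break_at + 1``)."""
    wt = truth.wt_seq
    if not 1 <= break_at < len(wt):
        raise ValueError("break position outside the genome")
    layout = [
        ContigPiece(names[0], 1, break_at, "+"),
        ContigPiece(names[1], break_at + 1, len(wt), "-" if invert_second else "+"),
    ]
    seq2 = wt[break_at:]
    reference = {
        names[0]: wt[:break_at],
        names[1]: revcomp(seq2) if invert_second else seq2,
    }
    return reference, layout


# ---------------------------------------------------------------------------
# evaluation


def evaluate_calls(
    truth: GenomeTruth,
    calls: Iterable[ProphageCandidate],
    tol: int = 2,
) -> dict:
    """Compare pipeline calls with the known att quad.

    A call hits when all four endpoints lie within ``tol`` of the truth.
    """
    t = truth.truth_quad.endpoints()
    best = None
    for c in calls:
        pts = (c.attL_start, c.attL_end, c.attR_start, c.attR_end)
        dev = max(abs(p - q) for p, q in zip(pts, t))
        if best is None or dev < best[0]:
            best = (dev, c)
    hit = best is not None and best[0] <= tol
    return {
        "hit": hit,
        "exact": best is not None and best[0] == 0,
        "max_deviation": None if best is None else best[0],
        "n_calls": sum(1 for _ in calls) if not isinstance(calls, list) else len(calls),
        "best_call": None if best is None else best[1],
    }


def sensitivity(hits: Sequence[Sequence[bool]]) -> float:
    """Average positive-hit fraction over rounds of replicate genomes."""
    if not hits:
        return float("nan")
    return float(np.mean([np.mean([1.0 if h else 0.0 for h in r]) for r in hits]))


# ---------------------------------------------------------------------------
# fixture output


def write_fixture(truth: GenomeTruth, outdir: str,
                  layout: Sequence[ContigPiece] | None = None) -> dict:
    """Write FASTA / FASTQ / truth SAM / manifest for one simulation."""
    os.makedirs(outdir, exist_ok=True)
    p = truth.params
    pairs, records = simulate_read_mixture(truth, layout=layout)

    def _fa(path, entries):
        with open(path, "w") as fh:
            for name, seq in entries:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    _fa(os.path.join(outdir, "reference.fasta"), [("chr", truth.wt_seq)])
    _fa(
        os.path.join(outdir, "molecules.fasta"),
        [
            ("wt", truth.wt_seq),
            ("excised_attB", truth.excised_seq),
            ("circular_attP", truth.circular_seq),
        ],
    )
    for mate in (1, 2):
        with open(os.path.join(outdir, f"reads_R{mate}.fastq"), "w") as fh:
            for i, pr in enumerate(pairs):
                seq = pr.seq1 if mate == 1 else pr.seq2
                fh.write(f"@sim{i}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
    reference = {"chr": truth.wt_seq}
    write_sam(records, os.path.join(outdir, "truth.sam"), reference)
    manifest = {
        "params": {
            k: getattr(p, k)
            for k in (
                "genome_len", "gc", "att_len", "att_mismatches", "prophage_size",
                "ratios", "depth", "read_len", "insert_mean", "insert_sd",
                "error_rate", "seed",
            )
        },
        "truth_quad": {
            "ref_name": truth.truth_quad.ref_name,
            "attL_start": truth.truth_quad.attL_start,
            "attL_end": truth.truth_quad.attL_end,
            "attR_start": truth.truth_quad.attR_start,
            "attR_end": truth.truth_quad.attR_end,
        },
        "n_pairs": len(pairs),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
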