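"""Overlapping split-read verification and att endpoint inference.

A read spanning an attB or attP junction aligns in two local pieces
whose *query* intervals overlap: the prefix piece R1–R2 and the suffix
piece R3–R4 satisfy R1 < R3 < R2 < R4, and the overlap R3..R2 is the att
core shared by attL and attR.  This module re-aligns preliminary split
candidates against the reference to find that second piece, enforces the
overlap criterion, classifies the junction as attB (read jumps forward
over the excised prophage) or attP (read crosses the circular-phage
junction backwards), and converts the segment endpoints into the four
attachment-site coordinates.

Re-alignment strategy: the primary piece is taken from the record's own
CIGAR; the soft-clipped flank is placed by fast infix (glocal) alignment
(edlib) within windows around the mapped position and the mate position,
then extended base-by-base across the att core with a small mismatch
budget.  The extension length *is* the query overlap.  Candidate
placements are ranked by total aligned query length, then summed
identity, then smallest reference coordinate, for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import edlib

from .detect import SplitCandidate
from .sam_io import cigar_clip_profile

__all__ = [
    "SegmentAlignment",
    "JunctionEvidence",
    "AttQuad",
    "RealignConfig",
    "realign_split_read",
    "classify_junction",
    "infer_att_endpoints",
    "verify_candidates",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(slots=True, frozen=True)
class SegmentAlignment:
    """One local alignment of part of a read: 1-based inclusive intervals."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    ref_name: str
    strand: str = "+"
    identity: float = 1.0

    def __post_init__(self):
        if self.q_start > self.q_end or self.r_start > self.r_end:
            raise ValueError("degenerate segment interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


@dataclass(slots=True, frozen=True)
class AttQuad:
    """The four attachment-site coordinates of one candidate prophage.

    ``attL`` and ``attR`` are the two copies of the att core flanking the
    integrated prophage; both spans have equal length.  For the
    same-reference case attL lies strictly upstream of attR.
    """

    ref_name: str
    attL_start: int
    attL_end: int
    attR_start: int
    attR_end: int

    def __post_init__(self):
        if not (self.attL_start <= self.attL_end < self.attR_start <= self.attR_end):
            raise ValueError("att quad ordering violated")
        if self.attL_end - self.attL_start != self.attR_end - self.attR_start:
            raise ValueError("attL and attR core lengths differ")

    @property
    def att_len(self) -> int:
        return self.attL_end - self.attL_start + 1

    @property
    def size(self) -> int:
        return self.attR_start - self.attL_start

    def endpoints(self) -> tuple[int, int, int, int]:
        return (self.attL_start, self.attL_end, self.attR_start, self.attR_end)


@dataclass(slots=True)
class JunctionEvidence:
    read_id: str
    jtype: Literal["attB", "attP"]
    left: SegmentAlignment
    right: SegmentAlignment
    ov: int
    quad: AttQuad


@dataclass(slots=True, frozen=True)
class RealignConfig:
    window: int = 200_000          # bp searched either side of mapped/mate positions
    min_segment: int = 10          # minimum length of each local alignment piece
    min_identity: float = 0.95     # per-segment identity floor
    ext_match: int = 1             # extension scoring across the att core
    ext_mismatch: int = -2
    ext_xdrop: int = 6             # stop once the score falls this far below its max
    min_overlap: int = 1           # strict criterion: R2 >= R3
    search_reverse: bool = False   # also place the clip on the reverse strand


def _windows(ref_len: int, centers: Iterable[int], half: int) -> list[tuple[int, int]]:
    """Merged 0-based half-open windows around the given 1-based centres."""
    spans = sorted(
        (max(0, c - 1 - half), min(ref_len, c + half)) for c in centers if c > 0
    )
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _extend(seq: str, qi: int, ref: str, ri: int, step: int, limit: int,
            cfg: "RealignConfig") -> int:
    """Ungapped X-drop extension comparing seq from qi and ref from ri in
    the given direction (0-based indices, step +1/-1).

    Returns the extension length at the strict score maximum: the
    extension ends where the running score (+match/-mismatch) last
    reached a new maximum, and aborts once it falls ``ext_xdrop`` below
    that maximum.  The strict maximum means an accidental match beyond
    the true repeat cannot be absorbed across an intervening mismatch,
    while internal att-copy mismatches are crossed whenever the
    remaining core re-raises the score."""
    best_k = 0
    best_score = 0
    score = 0
    k = 0
    while k < limit:
        q, r = qi + step * k, ri + step * k
        if q < 0 or r < 0 or q >= len(seq) or r >= len(ref):
            break
        score += cfg.ext_match if seq[q] == ref[r] else cfg.ext_mismatch
        k += 1
        if score > best_score:
            best_score = score
            best_k = k
        elif score <= best_score - cfg.ext_xdrop:
            break
    return best_k


def _segment_identity(seq: str, q0: int, q1: int, ref: str, r0: int) -> float:
    """Ungapped identity of seq[q0:q1] vs ref starting at r0 (0-based)."""
    n = q1 - q0
    if n <= 0:
        return 0.0
    matches = sum(1 for i in range(n) if r0 + i < len(ref) and seq[q0 + i] == ref[r0 + i])
    return matches / n


def realign_split_read(
    cand: SplitCandidate,
    reference: dict[str, str],
    config: RealignConfig = RealignConfig(),
) -> tuple[SegmentAlignment, SegmentAlignment] | None:
    """Verify a split candidate by locating its clipped flank.

    Returns the two segment alignments ordered by query start, or
    ``None`` when no placement satisfies the overlap criterion.  The
    search space is the union of windows around the record's own mapped
    position and its mate's position (the att partner locus lies within
    a prophage length of one of them).
    """
    rec = cand.record
    if rec.query_seq is None or not rec.is_mapped or not rec.cigar:
        return None
    if rec.ref_name not in reference:
        raise KeyError(f"reference sequence {rec.ref_name!r} not found")
    seq = rec.query_seq
    prof = cand.profile or cigar_clip_profile(rec.cigar)
    lead, aligned_q, tail = prof
    if lead and tail:
        return None
    # hard-clipped flanks are absent from SEQ and cannot be re-aligned
    if rec.query_length != len(seq):
        return None

    ref = reference[rec.ref_name]
    ref_span = rec.reference_span
    if cand.clip_side == "left":
        clip = seq[:lead]
        prim_q = (lead + 1, lead + aligned_q)
    else:
        clip = seq[len(seq) - tail:]
        prim_q = (1, aligned_q)
    if len(clip) < config.min_segment:
        return None
    prim = SegmentAlignment(
        q_start=prim_q[0],
        q_end=prim_q[1],
        r_start=rec.pos,
        r_end=rec.pos + ref_span - 1,
        ref_name=rec.ref_name,
        strand="+",
        identity=_segment_identity(seq, prim_q[0] - 1, prim_q[1], ref, rec.pos - 1),
    )

    max_dist = int((1.0 - config.min_identity) * len(clip))
    centers_by_ref: dict[str, list[int]] = {rec.ref_name: [rec.pos]}
    if rec.mate_is_mapped and rec.mate_ref_name in reference:
        centers_by_ref.setdefault(rec.mate_ref_name, []).append(rec.mate_pos)
    if cand.mode == "contig":
        # junction partner may sit on any contig of a draft assembly
        for name in reference:
            centers_by_ref.setdefault(name, [len(reference[name]) // 2])

    placements: list[tuple[tuple, SegmentAlignment, SegmentAlignment]] = []
    for ref2_name, centers in centers_by_ref.items():
        ref2 = reference[ref2_name]
        half = max(config.window, len(ref2)) if len(ref2) <= 2 * config.window else config.window
        for w0, w1 in _windows(len(ref2), centers, half):
            window_seq = ref2[w0:w1]
            strands = ["+"] + (["-"] if config.search_reverse else [])
            for strand in strands:
                target = window_seq if strand == "+" else revcomp(window_seq)
                aln = edlib.align(clip, target, mode="HW", task="locations", k=max_dist)
                if aln["editDistance"] < 0:
                    continue
                dist = aln["editDistance"]
                for loc in aln["locations"]:
                    s2, e2 = loc[0], loc[1]  # 0-based inclusive within target
                    pair = _build_pair(
                        cand, seq, prim, clip, dist,
                        ref2_name, ref2, w0, w1, s2, e2, strand, config,
                    )
                    if pair is not None:
                        placements.append(pair)
    if not placements:
        return None
    placements.sort(key=lambda t: t[0])
    return placements[0][1], placements[0][2]


def _build_pair(
    cand: SplitCandidate,
    seq: str,
    prim: SegmentAlignment,
    clip: str,
    clip_dist: int,
    ref2_name: str,
    ref2: str,
    w0: int,
    w1: int,
    s2: int,
    e2: int,
    strand: str,
    config: RealignConfig,
):
    """Extend one clip placement across the att core and assemble the
    ordered segment pair, or return ``None`` if the overlap criterion
    fails.  ``s2``/``e2`` are 0-based inclusive clip coordinates within
    the search target (the window, reverse-complemented for strand "-");
    all extension arithmetic stays in target coordinates and is mapped
    back to forward reference coordinates at the end."""
    lead = prim.q_start - 1
    aligned_q = prim.q_end - prim.q_start + 1
    n = w1 - w0
    target = ref2[w0:w1] if strand == "+" else revcomp(ref2[w0:w1])

    if cand.clip_side == "left":
        # clip is the query prefix; the second piece extends rightwards
        # from the clip into the primary-aligned part, across the core
        ov = _extend(seq, lead, target, e2 + 1, +1, aligned_q - 1, config)
        if ov < config.min_overlap:
            return None
        t_s, t_e = s2, e2 + ov
        q_s, q_e = 1, lead + ov
        clip_len = lead
    else:
        # clip is the query suffix; the second piece extends leftwards
        tail_len = len(seq) - prim.q_end
        ov = _extend(seq, prim.q_end - 1, target, s2 - 1, -1, aligned_q - 1, config)
        if ov < config.min_overlap:
            return None
        t_s, t_e = s2 - ov, e2
        q_s, q_e = prim.q_end - ov + 1, len(seq)
        clip_len = tail_len
    if t_s < 0 or t_e >= n:
        return None
    if strand == "+":
        r_start, r_end = w0 + t_s + 1, w0 + t_e + 1
    else:
        r_start, r_end = w0 + (n - 1 - t_e) + 1, w0 + (n - 1 - t_s) + 1
    sec = SegmentAlignment(
        q_start=q_s, q_end=q_e,
        r_start=r_start, r_end=r_end,
        ref_name=ref2_name, strand=strand,
        identity=1.0 - clip_dist / max(1, clip_len + ov),
    )
    if cand.clip_side == "left":
        first, second = sec, prim
    else:
        first, second = prim, sec

    # overlap criterion R1 < R3 < R2 < R4 and minimum piece lengths
    if not (first.q_start < second.q_start < first.q_end < second.q_end):
        return None
    if (first.q_end - first.q_start + 1) < config.min_segment:
        return None
    if (second.q_end - second.q_start + 1) < config.min_segment:
        return None
    if min(first.identity, second.identity) < config.min_identity:
        return None
    # identical locus: not a junction (same reference span)
    if first.ref_name == second.ref_name and not (
        first.r_end < second.r_start or second.r_end < first.r_start
    ):
        return None
    total_q = (first.q_end - first.q_start + 1) + (second.q_end - second.q_start + 1)
    rank = (-total_q, -(first.identity + second.identity),
            min(first.r_start, second.r_start), first.ref_name, second.ref_name)
    return rank, first, second


def classify_junction(
    left: SegmentAlignment, right: SegmentAlignment
) -> Literal["attB", "attP"] | None:
    """attB when the query prefix maps upstream of the suffix (the read
    jumps forward over the excised prophage); attP when it maps
    downstream (the read wraps backwards across the circular junction).
    Cross-reference or same-locus pairs are not classifiable here."""
    if left.ref_name != right.ref_name or left.strand != right.strand:
        return None
    if left.r_end < right.r_start:
        return "attB"
    if right.r_end < left.r_start:
        return "attP"
    return None


def infer_att_endpoints(
    left: SegmentAlignment,
    right: SegmentAlignment,
    jtype: Literal["attB", "attP"],
    ov: int,
) -> AttQuad:
    """Convert the two segment endpoints into the att quad.

    For attB evidence the prefix piece ends at attL_end and the suffix
    piece starts at attR_start; the overlap length fixes the other two
    coordinates.  attP evidence is the mirrored circular geometry.
    """
    if jtype == "attB":
        attL_end = left.r_end
        attR_start = right.r_start
        return AttQuad(
            ref_name=left.ref_name,
            attL_start=attL_end - ov + 1,
            attL_end=attL_end,
            attR_start=attR_start,
            attR_end=attR_start + ov - 1,
        )
    attR_end = left.r_end
    attL_start = right.r_start
    return AttQuad(
        ref_name=left.ref_name,
        attL_start=attL_start,
        attL_end=attL_start + ov - 1,
        attR_start=attR_end - ov + 1,
        attR_end=attR_end,
    )


def verify_candidates(
    candidates: Iterable[SplitCandidate],
    reference: dict[str, str],
    config: RealignConfig = RealignConfig(),
) -> tuple[list[JunctionEvidence], list[tuple[SplitCandidate, SegmentAlignment, SegmentAlignment]], dict[str, int]]:
    """Run re-alignment over all candidates.

    Returns same-reference junction evidence, the cross-reference
    segment pairs (handed to contig-mode assembly), and a counter of
    discarded candidates by reason.
    """
    evidence: list[JunctionEvidence] = []
    cross: list[tuple[SplitCandidate, SegmentAlignment, SegmentAlignment]] = []
    dropped = {"unverified": 0, "unclassifiable": 0, "bad_quad": 0}
    for cand in candidates:
        pair = realign_split_read(cand, reference, config)
        if pair is None:
            dropped["unverified"] += 1
            continue
        left, right = pair
        ov = left.q_end - right.q_start + 1
        if left.ref_name != right.ref_name:
            cross.append((cand, left, right))
            continue
        jtype = classify_junction(left, right)
        if jtype is None:
            dropped["unclassifiable"] += 1
            continue
        try:
            quad = infer_att_endpoints(left, right, jtype, ov)
        except ValueError:
            dropped["bad_quad"] += 1
            continue
        evidence.append(
            JunctionEvidence(cand.record.query_name, jtype, left, right, ov, quad)
        )
    return evidence, cross, dropped
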