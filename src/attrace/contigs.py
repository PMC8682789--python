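"""Cross-contig prophage detection for draft assemblies.

When an intact prophage sits at the termini of two contigs, the attL and
attR copies fall on different sequences and a junction read's two pieces
map to different contigs.  This module clusters such cross-reference
segment pairs, orients the two contigs into a common frame (attL carrier
with its junction-facing end on the right, attR carrier following with
its junction on the left), estimates the approximate prophage span
through the contig break, and reports candidates with a junction
annotation using '::' between contig names and '=' marking the
junction-facing side of each contig.

Which of the two jump directions is the excision (attB) junction and
which the circular (attP) junction cannot be read off the local
geometry alone: the two interpretations are mirror images.  The span
implied by each interpretation breaks the tie — the direction whose
implied prophage span is plausible (at most the maximum prophage size,
while the other is not) is taken as attB; evidence where both or
neither interpretation is plausible is reported as ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

from .candidates import FilterConfig
from .detect import DiscordantCandidate, SplitCandidate
from .realign import SegmentAlignment

__all__ = ["CrossContigCandidate", "detect_cross_contig_candidates"]


@dataclass(slots=True)
class CrossContigCandidate:
    """A candidate prophage spanning two contigs.

    ``contig_a`` carries attL (in the resolved interpretation),
    ``contig_b`` carries attR; coordinates are on each contig's own
    forward strand.  ``approx_size`` underestimates the true prophage
    size whenever further sequence intervenes between the two contigs.
    """

    name: str
    contig_a: str
    attL_start: int
    attL_end: int
    contig_b: str
    attR_start: int
    attR_end: int
    orientation: str          # one of "A+B+", "A+B-", "A-B+", "A-B-"
    approx_size: int
    att_len: int
    sr_attB: int
    sr_attP: int
    sr_ambiguous: int
    drp_attB: int
    drp_attP: int
    junction_annotation: str
    evidence_alignments: str = ""


def _att_interval(seg: SegmentAlignment, role: Literal["prefix", "suffix"], ov: int):
    """The att core occupies the junction-proximal ``ov`` bases of the
    segment, in forward contig coordinates."""
    if role == "prefix":
        if seg.strand == "+":
            return seg.r_end - ov + 1, seg.r_end
        return seg.r_start, seg.r_start + ov - 1
    if seg.strand == "+":
        return seg.r_start, seg.r_start + ov - 1
    return seg.r_end - ov + 1, seg.r_end


def _oriented_attL_gap(att: tuple[int, int], side: str, length: int) -> int:
    """Bases from attL_start to the junction end of its contig."""
    if side == "right":
        return length - att[0]
    # junction at the left: flip the contig
    return length - (length - att[1] + 1)


def _oriented_attR_gap(att: tuple[int, int], side: str, length: int) -> int:
    """Bases from the junction end of the attR contig to attR_start."""
    if side == "left":
        return att[0]
    return length - att[1] + 1


@dataclass(slots=True)
class _Evidence:
    read_id: str
    prefix_contig: str
    suffix_contig: str
    att_prefix: tuple[int, int]
    att_suffix: tuple[int, int]
    strands: tuple[str, str]  # (prefix piece, suffix piece)
    ov: int


def detect_cross_contig_candidates(
    cross_pairs: Iterable[tuple[SplitCandidate, SegmentAlignment, SegmentAlignment]],
    drps: list[DiscordantCandidate],
    reference: dict[str, str],
    cfg: FilterConfig = FilterConfig(),
) -> list[CrossContigCandidate]:
    """Cluster cross-contig junction evidence into candidates.

    Only the maximum-size filter applies (the approximate span is an
    underestimate, so the lower bound is waived); the att-length filter
    is kept.  Event-count filtering uses the total across both
    interpretations, since single-direction evidence cannot prove both
    junctions.
    """
    evidence: list[_Evidence] = []
    for cand, left, right in cross_pairs:
        for seg in (left, right):
            if seg.ref_name not in reference:
                raise KeyError(f"segment contig {seg.ref_name!r} not in reference")
        ov = left.q_end - right.q_start + 1
        if ov < 1:
            continue
        evidence.append(
            _Evidence(
                read_id=cand.record.query_name,
                prefix_contig=left.ref_name,
                suffix_contig=right.ref_name,
                att_prefix=_att_interval(left, "prefix", ov),
                att_suffix=_att_interval(right, "suffix", ov),
                strands=(left.strand, right.strand),
                ov=ov,
            )
        )

    # group by unordered contig pair, then by agreeing att endpoints
    clusters: list[list[_Evidence]] = []
    tol = cfg.cluster_tol
    for ev in sorted(
        evidence,
        key=lambda e: (tuple(sorted((e.prefix_contig, e.suffix_contig))),
                       e.att_prefix, e.att_suffix),
    ):
        placed = False
        for cl in clusters:
            m = cl[0]
            if {ev.prefix_contig, ev.suffix_contig} != {m.prefix_contig, m.suffix_contig}:
                continue
            if ev.prefix_contig == m.prefix_contig:
                pairs = ((ev.att_prefix, m.att_prefix), (ev.att_suffix, m.att_suffix))
            else:  # opposite jump direction: prefix matches the other att
                pairs = ((ev.att_prefix, m.att_suffix), (ev.att_suffix, m.att_prefix))
            if all(
                abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol
                for a, b in pairs
            ):
                cl.append(ev)
                placed = True
                break
        if not placed:
            clusters.append([ev])

    out: list[CrossContigCandidate] = []
    for cl in clusters:
        cand = _summarize_cluster(cl, drps, reference, cfg)
        if cand is None:
            continue
        if cand.att_len <= cfg.min_att_len:
            continue
        if cand.approx_size >= cfg.max_size:
            continue
        if cand.sr_attB + cand.sr_attP + cand.sr_ambiguous + cand.drp_attB + cand.drp_attP < 1:
            continue
        out.append(cand)
    out.sort(key=lambda c: (c.contig_a, c.attL_start))
    for i, c in enumerate(out, start=1):
        c.name = f"X{i}"
    return out


def _modal_pair(values: list[tuple[int, int]]) -> tuple[int, int]:
    counts = Counter(values)
    return max(counts.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))[0]


def _evidence_dirs(e: _Evidence, x: str) -> tuple[str, str]:
    """Junction-facing direction on contigs (x, y) implied by one
    evidence item: the query runs off the end of the prefix piece
    (rightwards on '+', leftwards on '-') and arrives into the suffix
    piece from the opposite side.  This signature is invariant under
    read-orientation flips, unlike the jump direction itself."""
    dir_prefix = "right" if e.strands[0] == "+" else "left"
    dir_suffix = "left" if e.strands[1] == "+" else "right"
    if e.prefix_contig == x:
        return dir_prefix, dir_suffix
    return dir_suffix, dir_prefix


def _summarize_cluster(cl, drps, reference, cfg) -> CrossContigCandidate | None:
    x, y = sorted({cl[0].prefix_contig, cl[0].suffix_contig})
    lx, ly = len(reference[x]), len(reference[y])

    # consensus att interval on each contig, from evidence in either direction
    att_x = _modal_pair(
        [e.att_prefix if e.prefix_contig == x else e.att_suffix for e in cl]
    )
    att_y = _modal_pair(
        [e.att_suffix if e.prefix_contig == x else e.att_prefix for e in cl]
    )
    ov = Counter(e.ov for e in cl).most_common(1)[0][0]

    # Each evidence item supports one of two complementary adjacencies
    # (the excision junction and the circular junction of the same
    # prophage).  The adjacency is identified by its direction
    # signature; its implied prophage span runs from each att towards
    # the junction-facing contig end.  The span is invariant under the
    # (locally undecidable) attL/attR labelling, so it is computed with
    # attL arbitrarily placed on the lexicographically first contig.
    sig_counts = Counter(_evidence_dirs(e, x) for e in cl)
    sig = sig_counts.most_common(1)[0][0]
    sig_comp = tuple("left" if d == "right" else "right" for d in sig)

    def span(signature):
        dx, dy = signature
        return _oriented_attL_gap(att_x, dx, lx) + _oriented_attR_gap(att_y, dy, ly)

    size_sig, size_comp = span(sig), span(sig_comp)
    sig_ok = 0 < size_sig < cfg.max_size
    comp_ok = 0 < size_comp < cfg.max_size
    if sig_ok == comp_ok:
        # both or neither span plausible: deterministic output (smaller
        # span taken as the excision side) but evidence stays ambiguous
        ambiguous = True
        attB_sig = sig if size_sig <= size_comp else sig_comp
    else:
        ambiguous = False
        attB_sig = sig if sig_ok else sig_comp

    # attL/attR roles across contigs are a reporting convention (see
    # module docstring); contig_a is the first contig, carrying attL
    a_name, b_name = x, y
    att_a, att_b = att_x, att_y
    side_a, side_b = attB_sig
    approx = span(attB_sig)

    n_attB = sum(n for s, n in sig_counts.items() if s == attB_sig)
    n_attP = len(cl) - n_attB
    if ambiguous:
        sr_attB = sr_attP = 0
        sr_amb = len(cl)
    else:
        sr_attB, sr_attP, sr_amb = n_attB, n_attP, 0

    drp_attB, drp_attP = _count_cross_drps(
        drps, a_name, b_name, att_a, att_b, side_a, side_b, reference, cfg.drp_window
    )

    # '=' marks the junction-facing side of a contig: 'name = ' for a
    # right junction, ' = name' for a left one (unmarked in the
    # canonical right::left case where '::' already implies it)
    tok_a = f"{a_name} = " if side_a == "right" else f" = {a_name}"
    tok_b = b_name if side_b == "left" else f"{b_name} = "
    annotation = f"{tok_a}::{tok_b}"
    orientation = "A" + ("+" if side_a == "right" else "-") + \
                  "B" + ("+" if side_b == "left" else "-")

    ev_lines = [
        f"{e.read_id}\t{e.prefix_contig}:{e.att_prefix[0]}-{e.att_prefix[1]}"
        f" -> {e.suffix_contig}:{e.att_suffix[0]}-{e.att_suffix[1]} | ov={e.ov}"
        for e in cl
    ]
    return CrossContigCandidate(
        name="",
        contig_a=a_name,
        attL_start=att_a[0],
        attL_end=att_a[1],
        contig_b=b_name,
        attR_start=att_b[0],
        attR_end=att_b[1],
        orientation=orientation,
        approx_size=approx,
        att_len=ov,
        sr_attB=sr_attB,
        sr_attP=sr_attP,
        sr_ambiguous=sr_amb,
        drp_attB=drp_attB,
        drp_attP=drp_attP,
        junction_annotation=annotation,
        evidence_alignments="\n".join(ev_lines),
    )


def _count_cross_drps(drps, a_name, b_name, att_a, att_b, side_a, side_b,
                      reference, window) -> tuple[int, int]:
    """Count discordant pairs supporting the cross-contig junction.

    Both contigs are mapped into a common oriented frame (attL contig
    junction-right, attR contig appended junction-left) and the
    chromosome-level pair-geometry rules applied there."""
    la, lb = len(reference[a_name]), len(reference[b_name])

    def frame(rec):
        if rec.ref_name == a_name:
            if side_a == "right":
                s, e = rec.pos, rec.reference_end
                rev = rec.is_reverse
            else:
                s, e = la - rec.reference_end + 1, la - rec.pos + 1
                rev = not rec.is_reverse
            return s, e, rev
        if rec.ref_name == b_name:
            if side_b == "left":
                s, e = rec.pos, rec.reference_end
                rev = rec.is_reverse
            else:
                s, e = lb - rec.reference_end + 1, lb - rec.pos + 1
                rev = not rec.is_reverse
            return la + s, la + e, rev
        return None

    attL = (att_a if side_a == "right" else (la - att_a[1] + 1, la - att_a[0] + 1))
    attR_raw = att_b if side_b == "left" else (lb - att_b[1] + 1, lb - att_b[0] + 1)
    attR = (la + attR_raw[0], la + attR_raw[1])

    by_name: dict[str, list] = {}
    for d in drps:
        if d.record.ref_name in (a_name, b_name):
            by_name.setdefault(d.record.query_name, []).append(d.record)
    n_attB = n_attP = 0
    for recs in by_name.values():
        frames = [frame(r) for r in recs]
        if len(frames) != 2 or any(f is None for f in frames):
            continue
        fwd = [f for f in frames if not f[2]]
        rev = [f for f in frames if f[2]]
        if len(fwd) != 1 or len(rev) != 1:
            continue
        (fs, fe, _), (rs, re_, _) = fwd[0], rev[0]
        if fe <= attL[1] and fe >= attL[0] - window and rs >= attR[0] and rs <= attR[1] + window:
            n_attB += 1
        elif (
            fe <= attR[1] and fe >= attR[0] - window and fe > attL[1]
            and rs >= attL[0] and rs <= attL[1] + window and rs < attR[0]
        ):
            n_attP += 1
    return n_attB, n_attP
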