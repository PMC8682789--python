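"""Clustering of junction evidence into candidate prophages and the
Table-shaped report.

Junction evidence items are grouped when all four att endpoints agree
within a small tolerance; the cluster consensus is the per-endpoint mode.
Discordant read pairs are then merged as secondary evidence: a pair
flanking the consensus boundaries from outside in deletion-spanning
orientation supports the excision (attB) junction, a pair lying inside
the prophage pointing outwards supports the circular (attP) junction.
Candidates passing the count/size/att-length filters are reported one
row each: name, reference, the four att coordinates, prophage size,
att core length and the four evidence counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .detect import DiscordantCandidate
from .realign import AttQuad, JunctionEvidence

__all__ = [
    "CandidateCluster",
    "ProphageCandidate",
    "FilterConfig",
    "cluster_evidence",
    "merge_discordant",
    "filter_candidates",
    "summarize_candidate",
    "render_report",
    "render_evidence",
]


@dataclass(slots=True, frozen=True)
class FilterConfig:
    """Candidate retention thresholds.

    ``min_att_len`` and the size bounds are exclusive, matching the
    published defaults (att length > 2 bp, 5000 < size < 150000 bp);
    event-count minima are inclusive.
    """

    min_att_len: int = 2
    min_size: int = 5_000
    max_size: int = 150_000
    min_attB_events: int = 1
    min_attP_events: int = 1
    cluster_tol: int = 2
    drp_window: int = 1_000

    def __post_init__(self):
        if self.min_size >= self.max_size:
            raise ValueError("min_size must be < max_size")
        for name in ("min_att_len", "min_size", "min_attB_events",
                     "min_attP_events", "cluster_tol", "drp_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(slots=True)
class CandidateCluster:
    consensus: AttQuad
    members: list[JunctionEvidence] = field(default_factory=list)
    drps: list[tuple[DiscordantCandidate, ...]] = field(default_factory=list)
    drp_attB: int = 0
    drp_attP: int = 0

    @property
    def sr_attB(self) -> int:
        return sum(1 for m in self.members if m.jtype == "attB")

    @property
    def sr_attP(self) -> int:
        return sum(1 for m in self.members if m.jtype == "attP")


@dataclass(slots=True)
class ProphageCandidate:
    """One output row: size = attR_start - attL_start (bp of host
    chromosome removed on excision), att_len = length of the att core."""

    name: str
    ref_name: str
    attL_start: int
    attL_end: int
    attR_start: int
    attR_end: int
    size: int
    att_len: int
    sr_attB: int
    sr_attP: int
    drp_attB: int
    drp_attP: int
    evidence_alignments: str = ""


def _modal(values: list[int]) -> int:
    """Most frequent value; ties broken towards the smallest coordinate."""
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def cluster_evidence(
    evidence: list[JunctionEvidence], tol: int = 2
) -> list[CandidateCluster]:
    """Group evidence whose four endpoints each agree within ``tol``.

    Single-link chaining is bounded: a new member must be within ``tol``
    of at least one existing member and within ``2 * tol`` of every
    member, so clusters cannot drift.  Consensus is the per-endpoint
    mode, ties towards the smaller coordinate.
    """
    by_ref: dict[str, list[JunctionEvidence]] = defaultdict(list)
    for ev in evidence:
        by_ref[ev.quad.ref_name].append(ev)

    clusters: list[CandidateCluster] = []
    for ref_name in sorted(by_ref):
        evs = sorted(by_ref[ref_name], key=lambda e: e.quad.endpoints())
        open_clusters: list[list[JunctionEvidence]] = []
        for ev in evs:
            pts = ev.quad.endpoints()
            placed = False
            for cl in open_clusters:
                near = any(
                    all(abs(p - q) <= tol for p, q in zip(pts, m.quad.endpoints()))
                    for m in cl
                )
                within = all(
                    all(abs(p - q) <= 2 * tol for p, q in zip(pts, m.quad.endpoints()))
                    for m in cl
                )
                if near and within:
                    cl.append(ev)
                    placed = True
                    break
            if not placed:
                open_clusters.append([ev])
        for cl in open_clusters:
            endpoints = list(zip(*(m.quad.endpoints() for m in cl)))
            consensus = AttQuad(
                ref_name,
                _modal(list(endpoints[0])),
                _modal(list(endpoints[1])),
                _modal(list(endpoints[2])),
                _modal(list(endpoints[3])),
            )
            clusters.append(CandidateCluster(consensus=consensus, members=cl))
    return clusters


def _pair_geometry(records: list[DiscordantCandidate]):
    """Forward/reverse read intervals of one discordant pair, or ``None``
    when the pair is not a plain forward+reverse combination."""
    fwd = [r for r in records if not r.record.is_reverse]
    rev = [r for r in records if r.record.is_reverse]
    if len(fwd) != 1 or len(rev) != 1:
        return None
    f, r = fwd[0].record, rev[0].record
    return (f.ref_name, f.pos, f.reference_end), (r.ref_name, r.pos, r.reference_end)


def merge_discordant(
    clusters: list[CandidateCluster],
    drps: list[DiscordantCandidate],
    window: int = 1_000,
) -> tuple[list[CandidateCluster], int]:
    """Attach discordant pairs to clusters as secondary evidence.

    Pairs are grouped by read name.  Each pair increments at most one
    counter of at most one cluster; a pair fitting several clusters goes
    to the one whose boundaries it brackets most tightly (smallest
    summed distance, ties towards the lower attL_start).  Returns the
    clusters and the number of pairs matching none.
    """
    by_name: dict[str, list[DiscordantCandidate]] = defaultdict(list)
    for d in drps:
        by_name[d.record.query_name].append(d)

    order = sorted(range(len(clusters)),
                   key=lambda i: (clusters[i].consensus.ref_name,
                                  clusters[i].consensus.attL_start))
    dropped = 0
    for name in sorted(by_name):
        group = by_name[name]
        geom = _pair_geometry(group)
        if geom is None:
            dropped += 1
            continue
        (f_ref, f_start, f_end), (r_ref, r_start, r_end) = geom
        best = None  # (distance, cluster index, kind)
        for i in order:
            q = clusters[i].consensus
            if f_ref != q.ref_name or r_ref != q.ref_name:
                continue
            # attB: pair flanks the prophage from outside (deletion span)
            if (
                f_end <= q.attL_end
                and f_end >= q.attL_start - window
                and r_start >= q.attR_start
                and r_start <= q.attR_end + window
                and f_start < r_start
            ):
                dist = max(0, q.attL_start - 1 - f_end) + max(0, r_start - q.attR_end - 1)
                cand = (dist, i, "attB")
                if best is None or cand < best:
                    best = cand
            # attP: pair lies inside the prophage pointing outwards
            # across the circular junction (everted orientation)
            if (
                f_end <= q.attR_end
                and f_end > q.attL_end
                and f_end >= q.attR_start - window
                and r_start >= q.attL_start
                and r_start < q.attR_start
                and r_start <= q.attL_end + window
                and r_start < f_start
            ):
                dist = max(0, q.attR_start - 1 - f_end) + max(0, r_start - q.attL_end - 1)
                cand = (dist, i, "attP")
                if best is None or cand < best:
                    best = cand
        if best is None:
            dropped += 1
            continue
        _, i, kind = best
        clusters[i].drps.append(tuple(group))
        if kind == "attB":
            clusters[i].drp_attB += 1
        else:
            clusters[i].drp_attP += 1
    return clusters, dropped


def filter_candidates(
    clusters: list[CandidateCluster], cfg: FilterConfig = FilterConfig()
) -> list[ProphageCandidate]:
    """Apply the default retention rules and emit sorted, named rows."""
    kept = []
    for cl in clusters:
        q = cl.consensus
        if q.att_len <= cfg.min_att_len:
            continue
        if not (cfg.min_size < q.size < cfg.max_size):
            continue
        if cl.sr_attB + cl.drp_attB < cfg.min_attB_events:
            continue
        if cl.sr_attP + cl.drp_attP < cfg.min_attP_events:
            continue
        kept.append(cl)
    kept.sort(key=lambda c: (c.consensus.ref_name, c.consensus.attL_start))
    out = []
    for i, cl in enumerate(kept, start=1):
        cand = summarize_candidate(cl)
        cand.name = f"P{i}"
        out.append(cand)
    return out


def summarize_candidate(cluster: CandidateCluster) -> ProphageCandidate:
    """Render one cluster as an output row.

    ``size`` is the attL_start→attR_start distance (the chromosome
    segment lost on excision, equal to the circularised phage length);
    ``att_len`` is the core length shared by attL and attR.
    """
    q = cluster.consensus
    return ProphageCandidate(
        name="",
        ref_name=q.ref_name,
        attL_start=q.attL_start,
        attL_end=q.attL_end,
        attR_start=q.attR_start,
        attR_end=q.attR_end,
        size=q.attR_start - q.attL_start,
        att_len=q.attL_end - q.attL_start + 1,
        sr_attB=cluster.sr_attB,
        sr_attP=cluster.sr_attP,
        drp_attB=cluster.drp_attB,
        drp_attP=cluster.drp_attP,
        evidence_alignments=render_evidence(cluster),
    )


def render_evidence(cluster: CandidateCluster) -> str:
    """Human-readable rendering of each member's overlapping alignments,
    for manual review of genes disrupted at the integration site."""
    lines = []
    for m in cluster.members:
        lines.append(
            f"{m.read_id}\t{m.jtype}\tq[{m.left.q_start}-{m.left.q_end}]"
            f"->{m.left.ref_name}:{m.left.r_start}-{m.left.r_end}"
            f" | q[{m.right.q_start}-{m.right.q_end}]"
            f"->{m.right.ref_name}:{m.right.r_start}-{m.right.r_end}"
            f" | ov={m.ov}"
        )
    return "\n".join(lines)


REPORT_COLUMNS = [
    "prophage", "contig", "attL_start", "attL_end", "attR_start", "attR_end",
    "size", "att_length", "SR_attB", "SR_attP", "DRP_attB", "DRP_attP",
]


def render_report(candidates: list[ProphageCandidate]):
    """Candidates as a DataFrame in the published column layout."""
    import pandas as pd

    rows = [
        {
            "prophage": c.name,
            "contig": c.ref_name,
            "attL_start": c.attL_start,
            "attL_end": c.attL_end,
            "attR_start": c.attR_start,
            "attR_end": c.attR_end,
            "size": c.size,
            "att_length": c.att_len,
            "SR_attB": c.sr_attB,
            "SR_attP": c.sr_attP,
            "DRP_attB": c.drp_attB,
            "DRP_attP": c.drp_attP,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
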