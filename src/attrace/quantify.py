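"""Between-condition fold-change of prophage excision from junction-read
counts.

The junction-read count of one prophage is not comparable across
prophages (it scales with the att length among other things), but for a
single prophage the evidence count normalised by library size is
proportional to the abundance of the excised or circular molecule, so
the ratio between two conditions estimates the excision-rate
fold-change.  A zero evidence count entering a dividend is replaced by
one (and flagged), keeping the ratio finite while remaining
conservative.

attB evidence (excision junction on the chromosome) is the direct
excision-rate proxy, mirroring attB-targeted qPCR; attP and combined
ratios are reported alongside since circular-phage replication can
amplify attP independently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidates import ProphageCandidate

__all__ = [
    "ConditionCounts",
    "FoldChangeResult",
    "fold_change",
    "counts_from_candidate",
    "primer_windows",
]


@dataclass(slots=True, frozen=True)
class ConditionCounts:
    """Evidence counts for one candidate under one condition, plus the
    library size used for normalisation (total reads in the SAM stream,
    mapped + unmapped, by default)."""

    sr_attB: int
    sr_attP: int
    drp_attB: int
    drp_attP: int
    total_reads: int

    def __post_init__(self):
        for name in ("sr_attB", "sr_attP", "drp_attB", "drp_attP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")

    @property
    def attB_events(self) -> int:
        return self.sr_attB + self.drp_attB

    @property
    def attP_events(self) -> int:
        return self.sr_attP + self.drp_attP

    @property
    def all_events(self) -> int:
        return self.attB_events + self.attP_events


@dataclass(slots=True, frozen=True)
class FoldChangeResult:
    fc_attB: float
    fc_attP: float
    fc_combined: float
    zero_substituted: dict[str, bool]

    def __post_init__(self):
        for v in (self.fc_attB, self.fc_attP, self.fc_combined):
            if not v > 0 or v != v or v in (float("inf"),):
                raise ValueError("fold changes must be positive and finite")


def counts_from_candidate(c: ProphageCandidate, total_reads: int) -> ConditionCounts:
    return ConditionCounts(c.sr_attB, c.sr_attP, c.drp_attB, c.drp_attP, total_reads)


def _ratio(treated_events: int, control_events: int,
           treated_total: int, control_total: int) -> tuple[float, bool]:
    substituted = False
    if treated_events == 0:
        treated_events = 1
        substituted = True
    if control_events == 0:
        control_events = 1
        substituted = True
    rate_t = treated_events / treated_total
    rate_c = control_events / control_total
    return rate_t / rate_c, substituted


def fold_change(treated: ConditionCounts, control: ConditionCounts) -> FoldChangeResult:
    """Fold-change of the normalised evidence rate, treated over control.

    Computed separately from attB evidence, attP evidence and their sum;
    any zero evidence count entering a dividend is replaced by one and
    the corresponding ratio flagged.  Library sizes are never
    substituted (they are nonzero by construction).
    """
    fb, sb = _ratio(treated.attB_events, control.attB_events,
                    treated.total_reads, control.total_reads)
    fp, sp = _ratio(treated.attP_events, control.attP_events,
                    treated.total_reads, control.total_reads)
    fc, sc = _ratio(treated.all_events, control.all_events,
                    treated.total_reads, control.total_reads)
    return FoldChangeResult(
        fc_attB=fb, fc_attP=fp, fc_combined=fc,
        zero_substituted={"attB": sb, "attP": sp, "combined": sc},
    )


def primer_windows(c: ProphageCandidate, flank: int = 150) -> list[tuple[str, int, int, str]]:
    """qPCR primer target windows as BED intervals (0-based half-open).

    One primer of each pair sits in the ``flank`` bp outside the
    junction on either side, so the amplicon spans the reconstituted
    attB (host flanks joined over the excised prophage) or attP (phage
    ends joined on the circle) junction with a product of roughly
    2 x flank plus the att core, i.e. 200-300 bp plus core at the
    default flank.
    """
    rows = []
    attB_l = (max(0, c.attL_start - 1 - flank), c.attL_start - 1)
    attB_r = (c.attR_end, c.attR_end + flank)
    attP_l = (max(c.attL_end, c.attR_start - 1 - flank), c.attR_start - 1)
    attP_r = (c.attL_end, min(c.attL_end + flank, c.attR_start - 1))
    rows.append((c.ref_name, attB_l[0], attB_l[1], f"{c.name}_attB_upstream"))
    rows.append((c.ref_name, attB_r[0], attB_r[1], f"{c.name}_attB_downstream"))
    rows.append((c.ref_name, attP_l[0], attP_l[1], f"{c.name}_attP_phage_left"))
    rows.append((c.ref_name, attP_r[0], attP_r[1], f"{c.name}_attP_phage_right"))
    return rows
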