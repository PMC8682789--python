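"""Preliminary extraction of split-read and discordant-pair candidates.

A read spanning an attB junction (prophage excised from the chromosome)
or an attP junction (circularised phage) cannot be aligned linearly: the
aligner soft-clips one flank.  The admissible (clip pattern, FLAG)
combinations below are exactly the configurations a junction-crossing
read of a paired FR library can produce, for chromosome-level references
and, with the extended sets, for junctions falling across two contigs of
a draft assembly.

Matching is by strict FLAG integer equality by default (reproducing the
published rule set); a lenient switch admits the same geometry expressed
with or without the 0x2 proper-pair bit, which different aligners set
differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .sam_io import AlignmentRecord, ClipProfile, cigar_clip_profile

__all__ = [
    "SplitCandidate",
    "DiscordantCandidate",
    "ClipBounds",
    "detect_split_candidate",
    "detect_discordant_candidate",
    "scan_alignments",
    "ScanResult",
]

Mode = Literal["chromosome", "contig"]

# FLAG sets admissible for a left-clipped (aSbM) split read and a
# right-clipped (aMbS) one, chromosome-level references.
SPLIT_LEFT_FLAGS = frozenset({145, 81, 99, 163})
SPLIT_RIGHT_FLAGS = frozenset({97, 161, 147, 83})
# Additional orientations occurring only when the two junction sides sit
# on different contigs (possibly in opposite assembly orientations).
SPLIT_LEFT_FLAGS_CONTIG = SPLIT_LEFT_FLAGS | {113, 117}
SPLIT_RIGHT_FLAGS_CONTIG = SPLIT_RIGHT_FLAGS | {65, 129}

DISCORDANT_FLAGS = frozenset({97, 145, 81, 161})
DISCORDANT_FLAGS_CONTIG = DISCORDANT_FLAGS | {177, 113, 129, 65}

# FLAG 117 carries the unmapped bit: the record has no CIGAR/POS of its
# own and is admitted (contig mode only) on the flag alone, to be
# resolved through its mapped mate.  It can never be re-aligned.
_UNMAPPED_SPLIT_FLAGS = frozenset({117})

_PROPER_MASK = ~0x2


@dataclass(slots=True, frozen=True)
class ClipBounds:
    """Admissible clip length ``a`` and aligned length ``b`` (inclusive).

    Defaults follow the 2x150 bp Illumina geometry: 10–150.  For other
    read lengths the lower bound stays at 10 and the upper bound is the
    read length.
    """

    lower: int = 10
    upper: int = 150

    @classmethod
    def for_read_length(cls, read_len: int) -> "ClipBounds":
        return cls(10, read_len)

    def admits(self, n: int) -> bool:
        return self.lower <= n <= self.upper


@dataclass(slots=True)
class SplitCandidate:
    record: AlignmentRecord
    clip_side: Literal["left", "right"]
    orientation_class: int
    mode: Mode
    profile: ClipProfile | None = None


@dataclass(slots=True)
class DiscordantCandidate:
    record: AlignmentRecord
    aligned_len: int
    orientation_class: int
    mode: Mode


def _flag_in(flag: int, flags: frozenset[int], lenient: bool) -> bool:
    if flag in flags:
        return True
    if lenient:
        masked = flag & _PROPER_MASK
        return any((f & _PROPER_MASK) == masked for f in flags)
    return False


def detect_split_candidate(
    rec: AlignmentRecord,
    mode: Mode = "chromosome",
    bounds: ClipBounds = ClipBounds(),
    lenient_flags: bool = False,
) -> SplitCandidate | None:
    """Return a preliminary split-read candidate, or ``None``.

    A candidate has exactly one terminal clip whose length ``a`` and
    aligned query length ``b`` both fall within ``bounds``, with a FLAG
    from the set admissible for that clip side.  Reads clipped at both
    ends are rejected: at a true att junction with ``a, b >= 10`` the
    second flank aligns, so two-sided clips are ambiguous evidence.
    """
    left_flags = SPLIT_LEFT_FLAGS_CONTIG if mode == "contig" else SPLIT_LEFT_FLAGS
    right_flags = SPLIT_RIGHT_FLAGS_CONTIG if mode == "contig" else SPLIT_RIGHT_FLAGS

    if mode == "contig" and rec.flag_raw in _UNMAPPED_SPLIT_FLAGS:
        # unmapped-by-flag record admitted on the flag alone (no CIGAR)
        return SplitCandidate(rec, "left", rec.flag_raw, mode, None)
    if not rec.is_mapped or not rec.cigar:
        return None
    try:
        prof = cigar_clip_profile(rec.cigar)
    except Exception:
        return None
    lead, aligned, tail = prof
    if lead > 0 and tail > 0:
        return None
    if lead > 0:
        if not (_flag_in(rec.flag_raw, left_flags, lenient_flags)
                and bounds.admits(lead) and bounds.admits(aligned)):
            return None
        return SplitCandidate(rec, "left", rec.flag_raw, mode, prof)
    if tail > 0:
        if not (_flag_in(rec.flag_raw, right_flags, lenient_flags)
                and bounds.admits(tail) and bounds.admits(aligned)):
            return None
        return SplitCandidate(rec, "right", rec.flag_raw, mode, prof)
    return None


def detect_discordant_candidate(
    rec: AlignmentRecord,
    mode: Mode = "chromosome",
    min_aligned: int = 130,
    lenient_flags: bool = False,
    require_cross_contig: bool = True,
) -> DiscordantCandidate | None:
    """Return a discordant-pair candidate, or ``None``.

    The record must align as a single unclipped match run longer than
    ``min_aligned`` with an orientation FLAG inconsistent with a
    concordant FR pair.  In contig mode the extended FLAG set is only
    accepted when the mate maps to a different contig (the same
    orientations on one contig are plain concordant pairs).
    """
    if not rec.is_mapped or len(rec.cigar) != 1 or rec.cigar[0][0] != "M":
        return None
    d = rec.cigar[0][1]
    if d <= min_aligned:
        return None
    flags = DISCORDANT_FLAGS_CONTIG if mode == "contig" else DISCORDANT_FLAGS
    if not _flag_in(rec.flag_raw, flags, lenient_flags):
        return None
    if (
        mode == "contig"
        and require_cross_contig
        and rec.flag_raw not in DISCORDANT_FLAGS
        and not _flag_in(rec.flag_raw, DISCORDANT_FLAGS, lenient_flags)
        and rec.mate_ref_name == rec.ref_name
    ):
        return None
    return DiscordantCandidate(rec, d, rec.flag_raw, mode)


@dataclass(slots=True)
class ScanResult:
    splits: list[SplitCandidate]
    discordants: list[DiscordantCandidate]
    n_records: int


def scan_alignments(
    records: Iterable[AlignmentRecord],
    mode: Mode = "chromosome",
    bounds: ClipBounds = ClipBounds(),
    min_aligned: int = 130,
    lenient_flags: bool = False,
    drop_duplicates: bool = False,
) -> ScanResult:
    """Single streaming pass extracting both candidate classes.

    ``drop_duplicates`` removes coordinate-identical records (same FLAG,
    position, CIGAR and mate position), for inputs that were not
    deduplicated upstream.
    """
    splits: list[SplitCandidate] = []
    discordants: list[DiscordantCandidate] = []
    seen: set[tuple] = set()
    n = 0
    for rec in records:
        n += 1
        if drop_duplicates:
            key = (rec.flag_raw, rec.ref_name, rec.pos, rec.cigar, rec.mate_pos)
            if key in seen:
                continue
            seen.add(key)
        # cheap pre-test: pure-M records can only be discordant
        if len(rec.cigar) == 1 and rec.cigar[0][0] == "M":
            d = detect_discordant_candidate(rec, mode, min_aligned, lenient_flags)
            if d is not None:
                discordants.append(d)
            continue
        s = detect_split_candidate(rec, mode, bounds, lenient_flags)
        if s is not None:
            splits.append(s)
    return ScanResult(splits, discordants, n)
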