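"""Semantic model of SAM alignment records.

Downstream junction-detection rules are written against decomposed FLAG
bits and CIGAR clip geometry rather than raw integers, so this module is
the single place where SAM (v1.6) encoding details live.  Coordinates are
1-based, fully closed intervals throughout, matching SAM text.

The normative input is SAM text; BAM is accepted as optional sugar via
pysam when available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "AlignmentRecord",
    "ClipProfile",
    "SamParseError",
    "parse_alignment_record",
    "record_to_sam_line",
    "parse_cigar",
    "cigar_to_string",
    "cigar_clip_profile",
    "read_alignments",
    "read_fasta",
    "write_sam",
    "FLAG_PAIRED",
    "FLAG_PROPER",
    "FLAG_UNMAPPED",
    "FLAG_MATE_UNMAPPED",
    "FLAG_REVERSE",
    "FLAG_MATE_REVERSE",
    "FLAG_FIRST",
    "FLAG_SECOND",
    "FLAG_SECONDARY",
    "FLAG_SUPPLEMENTARY",
]

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ops that consume the query / the reference
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


class SamParseError(ValueError):
    """A SAM alignment line that cannot be interpreted; names the bad field."""


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    if text == "*":
        return ()
    ops = []
    consumed = 0
    for m in _CIGAR_RE.finditer(text):
        ops.append((m.group(2), int(m.group(1))))
        consumed += m.end() - m.start()
    if consumed != len(text) or not ops:
        raise SamParseError(f"malformed CIGAR string: {text!r}")
    return tuple(ops)


def cigar_to_string(cigar: tuple[tuple[str, int], ...]) -> str:
    if not cigar:
        return "*"
    return "".join(f"{n}{op}" for op, n in cigar)


@dataclass(slots=True)
class AlignmentRecord:
    """One parsed SAM alignment line.

    ``pos`` and ``mate_pos`` are 1-based leftmost mapped coordinates;
    ``mate_ref_name`` has ``"="`` already resolved to ``ref_name``.
    ``query_seq`` is the forward-reference-strand sequence exactly as
    stored in the SEQ column, or ``None`` when SEQ is ``*``.
    """

    query_name: str
    flag_raw: int
    ref_name: str
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    mate_ref_name: str
    mate_pos: int
    tlen: int
    query_seq: str | None
    qual: str = "*"
    tags: tuple[str, ...] = field(default=(), repr=False)

    # -- decomposed FLAG bits ------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag_raw & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag_raw & FLAG_PROPER)

    @property
    def is_mapped(self) -> bool:
        return not self.flag_raw & FLAG_UNMAPPED

    @property
    def mate_is_mapped(self) -> bool:
        return not self.flag_raw & FLAG_MATE_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag_raw & FLAG_REVERSE)

    @property
    def mate_is_reverse(self) -> bool:
        return bool(self.flag_raw & FLAG_MATE_REVERSE)

    @property
    def is_first_in_pair(self) -> bool:
        return bool(self.flag_raw & FLAG_FIRST)

    @property
    def is_secondary_or_supplementary(self) -> bool:
        return bool(self.flag_raw & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag_raw & FLAG_DUP)

    # -- geometry -------------------------------------------------------
    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost mapped reference coordinate."""
        return self.pos + self.reference_span - 1

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)


class ClipProfile(NamedTuple):
    """Terminal clip geometry of a CIGAR: ``lead_clip, aligned_len, tail_clip``.

    ``aligned_len`` counts query bases consumed by non-clip ops; hard
    clips contribute to the clip lengths even though their sequence is
    absent from SEQ.
    """

    lead_clip: int
    aligned_len: int
    tail_clip: int


def cigar_clip_profile(cigar: tuple[tuple[str, int], ...]) -> ClipProfile:
    if not cigar:
        raise SamParseError("empty CIGAR has no clip profile")
    i, j = 0, len(cigar)
    lead = tail = 0
    while i < j and cigar[i][0] in "SH":
        lead += cigar[i][1]
        i += 1
    while j > i and cigar[j - 1][0] in "SH":
        tail += cigar[j - 1][1]
        j -= 1
    aligned = 0
    for op, n in cigar[i:j]:
        if op in "SH":
            raise SamParseError(f"internal clip in CIGAR: {cigar_to_string(cigar)}")
        if op in _QUERY_OPS:
            aligned += n
    return ClipProfile(lead, aligned, tail)


_MANDATORY = (
    "QNAME", "FLAG", "RNAME", "POS", "MAPQ", "CIGAR", "RNEXT", "PNEXT", "TLEN", "SEQ", "QUAL",
)


def parse_alignment_record(line: str) -> AlignmentRecord:
    """Parse one tab-delimited SAM alignment line (not a header line)."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(
            f"SAM line has {len(fields)} fields, 11 mandatory fields required"
        )
    try:
        flag = int(fields[1])
    except ValueError:
        raise SamParseError(f"non-integer FLAG: {fields[1]!r}") from None
    try:
        pos = int(fields[3])
    except ValueError:
        raise SamParseError(f"non-integer POS: {fields[3]!r}") from None
    try:
        mapq = int(fields[4])
    except ValueError:
        raise SamParseError(f"non-integer MAPQ: {fields[4]!r}") from None
    try:
        mate_pos = int(fields[7])
    except ValueError:
        raise SamParseError(f"non-integer PNEXT: {fields[7]!r}") from None
    try:
        tlen = int(fields[8])
    except ValueError:
        raise SamParseError(f"non-integer TLEN: {fields[8]!r}") from None
    cigar = parse_cigar(fields[5])
    seq = None if fields[9] == "*" else fields[9].upper()
    mate_ref = fields[6]
    if mate_ref == "=":
        mate_ref = fields[2]
    rec = AlignmentRecord(
        query_name=fields[0],
        flag_raw=flag,
        ref_name=fields[2],
        pos=pos,
        mapq=mapq,
        cigar=cigar,
        mate_ref_name=mate_ref,
        mate_pos=mate_pos,
        tlen=tlen,
        query_seq=seq,
        qual=fields[10],
        tags=tuple(fields[11:]),
    )
    if rec.is_mapped and pos < 1:
        raise SamParseError(f"mapped record with POS {pos} < 1")
    if seq is not None and cigar and rec.query_length != len(seq):
        raise SamParseError(
            f"CIGAR consumes {rec.query_length} query bases but SEQ is {len(seq)} nt"
        )
    return rec


def record_to_sam_line(rec: AlignmentRecord) -> str:
    mate_ref = rec.mate_ref_name
    if mate_ref == rec.ref_name and mate_ref != "*":
        mate_ref = "="
    fields = [
        rec.query_name,
        str(rec.flag_raw),
        rec.ref_name,
        str(rec.pos),
        str(rec.mapq),
        cigar_to_string(rec.cigar),
        mate_ref,
        str(rec.mate_pos),
        str(rec.tlen),
        rec.query_seq if rec.query_seq is not None else "*",
        rec.qual,
        *rec.tags,
    ]
    return "\t".join(fields)


def read_alignments(path: str, exclude_secondary: bool = True) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM text file (or BAM via pysam).

    Secondary/supplementary records are skipped by default: junction
    evidence is built from primary alignments plus re-alignment, and
    counting a read twice would inflate event counts.
    """
    if str(path).endswith(".bam"):
        yield from _read_bam(path, exclude_secondary)
        return
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("@"):
                continue
            rec = parse_alignment_record(line)
            if exclude_secondary and rec.is_secondary_or_supplementary:
                continue
            yield rec


def _read_bam(path: str, exclude_secondary: bool) -> Iterator[AlignmentRecord]:
    import pysam  # optional dependency

    with pysam.AlignmentFile(path, "rb") as bam:
        for a in bam:
            if exclude_secondary and (a.is_secondary or a.is_supplementary):
                continue
            yield parse_alignment_record(a.to_string())


def write_sam(records: Iterable[AlignmentRecord], path: str,
              reference: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        if reference:
            for name, seq in reference.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            fh.write(record_to_sam_line(rec) + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a multi-record FASTA; IDs are the first whitespace token."""
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
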