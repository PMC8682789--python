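"""Overlap verification, junction classification and att endpoint
inference.

The toy-genome tests build the junction geometry explicitly: a read
X-flank + core + Y-flank whose prefix (X+core) and suffix (core+Y) match
two distinct reference loci, so every expected value is known by
construction, and the re-aligner's output is additionally cross-checked
against an independent exhaustive/local-alignment oracle.
"""

import numpy as np
import pytest

from attrace.detect import detect_split_candidate
from attrace.realign import (
    SegmentAlignment,
    classify_junction,
    infer_att_endpoints,
    realign_split_read,
)
from attrace.sam_io import AlignmentRecord


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _record(flag, cigar, pos, seq, mate_pos=0):
    return AlignmentRecord(
        query_name="r", flag_raw=flag, ref_name="chr", pos=pos, mapq=60,
        cigar=cigar, mate_ref_name="chr", mate_pos=mate_pos, tlen=0,
        query_seq=seq,
    )


@pytest.fixture(scope="module")
def toy():
    """Reference with ...X.core... at locus A and ...core.Y... at locus B,
    and an attB-style junction read X[80] + core[20] + Y[50]."""
    rng = np.random.default_rng(123)
    x = _dna(rng, 80)
    core = _dna(rng, 20)
    y = _dna(rng, 50)
    spacer1 = _dna(rng, 400)
    spacer2 = _dna(rng, 3000)
    spacer3 = _dna(rng, 400)
    # sentinel bases keep the shared core maximal at exactly 20 bp
    first = next(b for b in "ACGT" if b != y[0])
    last = next(b for b in "ACGT" if b != x[-1])
    spacer2 = first + spacer2[1:-1] + last
    ref = spacer1 + x + core + spacer2 + core + y + spacer3
    read = x + core + y  # 150 nt
    locus_a_core_end = len(spacer1) + len(x) + len(core)        # = attL_end
    locus_b_core_start = len(spacer1) + len(x) + len(core) + len(spacer2) + 1
    return {
        "ref": {"chr": ref},
        "read": read,
        "attL_end": locus_a_core_end,
        "attR_start": locus_b_core_start,
        "core_len": len(core),
    }


def oracle_exact_placements(read, ref):
    """Independent oracle: all maximal exact substring placements of a
    read prefix/suffix, found by brute-force scanning."""
    hits = []
    n = len(read)
    for q0 in range(n):
        for q1 in range(q0 + 10, n + 1):
            sub = read[q0:q1]
            start = ref.find(sub)
            if start >= 0 and (
                (q0 == 0 or ref.find(read[q0 - 1: q1]) < 0)
                and (q1 == n or ref.find(read[q0: q1 + 1]) < 0)
            ):
                hits.append((q0 + 1, q1, start + 1, start + len(sub)))
    return hits


class TestRealign:
    def test_left_clip_junction_read(self, toy):
        # BWA-style primary on the suffix piece (core+Y), X soft-clipped
        rec = _record(99, (("S", 80), ("M", 70)), toy["attR_start"], toy["read"],
                      mate_pos=toy["attR_start"] + 300)
        cand = detect_split_candidate(rec)
        assert cand is not None
        pair = realign_split_read(cand, toy["ref"])
        assert pair is not None
        left, right = pair
        assert (left.q_start, left.q_end) == (1, 100)
        assert (right.q_start, right.q_end) == (81, 150)
        assert left.q_end - right.q_start + 1 == toy["core_len"]
        assert left.r_end == toy["attL_end"]
        assert right.r_start == toy["attR_start"]

    def test_right_clip_junction_read(self, toy):
        # primary on the prefix piece (X+core), Y soft-clipped
        pos = toy["attL_end"] - 100 + 1
        rec = _record(97, (("M", 100), ("S", 50)), pos, toy["read"],
                      mate_pos=toy["attR_start"] + 500)
        cand = detect_split_candidate(rec)
        pair = realign_split_read(cand, toy["ref"])
        assert pair is not None
        left, right = pair
        assert (left.q_start, left.q_end) == (1, 100)
        assert (right.q_start, right.q_end) == (81, 150)
        assert left.r_end == toy["attL_end"]
        assert right.r_start == toy["attR_start"]

    def test_agrees_with_exact_placement_oracle(self, toy):
        """Both re-aligned pieces must appear among the maximal exact
        placements found by brute force."""
        rec = _record(99, (("S", 80), ("M", 70)), toy["attR_start"], toy["read"])
        pair = realign_split_read(detect_split_candidate(rec), toy["ref"])
        hits = oracle_exact_placements(toy["read"], toy["ref"]["chr"])
        for seg in pair:
            assert (seg.q_start, seg.q_end, seg.r_start, seg.r_end) in hits

    def test_linear_read_with_spurious_clip_yields_none(self, toy):
        """A read matching one locus end-to-end has no second locus: the
        clip re-locates adjacent to the primary and is rejected."""
        ref = toy["ref"]["chr"]
        pos = 30
        read = ref[pos - 1: pos - 1 + 150]
        rec = _record(99, (("S", 40), ("M", 110)), pos + 40, read)
        cand = detect_split_candidate(rec)
        assert realign_split_read(cand, toy["ref"]) is None

    def test_abutting_split_without_overlap_yields_none(self):
        """A zero-length att core gives abutting, non-overlapping pieces
        which fail the strict overlap criterion."""
        rng = np.random.default_rng(5)
        x, y = _dna(rng, 80), _dna(rng, 70)
        sp = _dna(rng, 2000)
        ref = {"chr": _dna(rng, 300) + x + sp + y + _dna(rng, 300)}
        read = x + y
        pos = ref["chr"].find(y) + 1
        rec = _record(99, (("S", 80), ("M", 70)), pos, read)
        cand = detect_split_candidate(rec)
        assert realign_split_read(cand, toy := ref) is None

    def test_agrees_with_smith_waterman_oracle(self, toy):
        """Independent dual route: scored local alignment (match +1,
        mismatch -2, gap -3/-1) of the read against windows around the
        two loci reproduces the same two overlapping pieces."""
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-2,
            open_gap_score=-3, extend_gap_score=-1,
        )
        rec = _record(99, (("S", 80), ("M", 70)), toy["attR_start"], toy["read"])
        mine = realign_split_read(detect_split_candidate(rec), toy["ref"])
        ref = toy["ref"]["chr"]
        expected = []
        for centre in (toy["attL_end"], toy["attR_start"]):
            w0 = max(0, centre - 300)
            aln = aligner.align(ref[w0: centre + 300], toy["read"])[0]
            t_blocks, q_blocks = aln.aligned
            expected.append((
                q_blocks[0][0] + 1, q_blocks[-1][1],
                w0 + t_blocks[0][0] + 1, w0 + t_blocks[-1][1],
            ))
        got = [(s.q_start, s.q_end, s.r_start, s.r_end) for s in mine]
        assert got == expected

    def test_att_core_at_geometric_ceiling_is_recoverable(self):
        """A 130 bp core with 10 bp flanks on each side exactly fills a
        150 bp read: the ceiling of recoverable att lengths is set by
        read geometry, and a read at that limit still verifies."""
        rng = np.random.default_rng(77)
        u, core, d = _dna(rng, 300), _dna(rng, 130), _dna(rng, 300)
        sp = _dna(rng, 2000)
        ref = {"chr": u + core + sp + core + d}
        read = u[-10:] + core + d[:10]
        attR_start = len(u) + 130 + len(sp) + 1
        rec = _record(99, (("S", 10), ("M", 140)), attR_start, read)
        cand = detect_split_candidate(rec)
        assert cand is not None
        pair = realign_split_read(cand, ref)
        assert pair is not None
        left, right = pair
        assert left.q_end - right.q_start + 1 == 130
        # one base more core and the flanks drop below the 10 bp bound
        read_over = u[-10:] + _dna(rng, 131) + d[:9]
        rec_over = _record(99, (("S", 9), ("M", 141)), attR_start, read_over)
        assert detect_split_candidate(rec_over) is None

    def test_low_identity_clip_rejected(self, toy):
        rng = np.random.default_rng(9)
        read = _dna(rng, 80) + toy["read"][80:]  # prefix replaced by noise
        rec = _record(99, (("S", 80), ("M", 70)), toy["attR_start"], read)
        cand = detect_split_candidate(rec)
        assert realign_split_read(cand, toy["ref"]) is None


class TestClassification:
    def _seg(self, q0, q1, r0, r1, ref="chr"):
        return SegmentAlignment(q0, q1, r0, r1, ref)

    def test_attB_geometry(self):
        left = self._seg(1, 100, 785288 - 49, 785336)
        right = self._seg(81, 150, 797699, 797699 + 69)
        assert classify_junction(left, right) == "attB"

    def test_attP_geometry_is_mirrored(self):
        left = self._seg(1, 100, 797747 - 99, 797747)
        right = self._seg(81, 150, 785288, 785288 + 69)
        assert classify_junction(left, right) == "attP"

    def test_same_locus_overlap_not_classifiable(self):
        left = self._seg(1, 100, 100, 199)
        right = self._seg(81, 150, 150, 220)
        assert classify_junction(left, right) is None

    def test_cross_reference_deferred(self):
        left = self._seg(1, 100, 100, 199, ref="c1")
        right = self._seg(81, 150, 500, 569, ref="c2")
        assert classify_junction(left, right) is None

    def test_mirrored_call_never_same_type(self, toy_result):
        for ev in toy_result.evidence:
            mirrored = classify_junction(ev.right, ev.left)
            assert mirrored != classify_junction(ev.left, ev.right)


class TestEndpointInference:
    def test_attB_geometry_from_published_pf4_coordinates(self):
        left = SegmentAlignment(1, 100, 785240, 785336, "NC_002516.2")
        right = SegmentAlignment(52, 150, 797699, 797790, "NC_002516.2")
        quad = infer_att_endpoints(left, right, "attB", 49)
        assert quad.endpoints() == (785288, 785336, 797699, 797747)

    def test_attP_geometry_from_published_cp4so_coordinates(self):
        left = SegmentAlignment(1, 110, 1538050, 1538157, "NC_004347.2")
        right = SegmentAlignment(17, 150, 1501853, 1501990, "NC_004347.2")
        quad = infer_att_endpoints(left, right, "attP", 94)
        assert quad.endpoints() == (1501853, 1501946, 1538064, 1538157)

    def test_single_base_core(self):
        left = SegmentAlignment(1, 60, 941, 1000, "chr")
        right = SegmentAlignment(60, 150, 2000, 2090, "chr")
        quad = infer_att_endpoints(left, right, "attB", 1)
        assert quad.endpoints() == (1000, 1000, 2000, 2000)

    def test_quad_with_interleaved_att_copies_rejected(self):
        # attR_start would fall inside the attL interval
        left = SegmentAlignment(1, 60, 1941, 2000, "chr")
        right = SegmentAlignment(41, 150, 1995, 2104, "chr")
        with pytest.raises(ValueError):
            infer_att_endpoints(left, right, "attB", 20)


class TestSimulatedEvidence:
    def test_exact_truth_recovery_and_type_agreement(self, toy_truth, toy_result):
        """Error-free junction reads recover the truth quad exactly;
        attB- and attP-derived quads are identical; the overlap equals
        the simulated att core length."""
        evidence = toy_result.evidence
        assert evidence
        types = {ev.jtype for ev in evidence}
        assert types == {"attB", "attP"}
        for ev in evidence:
            assert ev.quad == toy_truth.truth_quad
            assert ev.ov == toy_truth.truth_quad.att_len

    def test_att_copy_mismatches_shift_endpoints_at_most_that_far(self):
        """With up to 2 mismatches between the att copies, inferred
        endpoints agree with truth within the mismatch distance."""
        from attrace.pipeline import run_trace_records
        from attrace.simulate import SimParams, simulate_prophage_genome, simulate_read_mixture

        p = SimParams(genome_len=80_000, att_len=40, att_mismatches=2,
                      prophage_size=15_000, ratios=(2, 1, 1), depth=50,
                      error_rate=0.0, seed=21)
        truth = simulate_prophage_genome(p)
        _, records = simulate_read_mixture(truth)
        res = run_trace_records(iter(records), {"chr": truth.wt_seq})
        assert res.evidence
        t = truth.truth_quad.endpoints()
        for ev in res.evidence:
            dev = max(abs(a - b) for a, b in zip(ev.quad.endpoints(), t))
            assert dev <= 2
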