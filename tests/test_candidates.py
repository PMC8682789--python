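"""Evidence clustering, discordant-pair merging, filtering and the
candidate report."""

import itertools

import pytest

from attrace.candidates import (
    CandidateCluster,
    FilterConfig,
    cluster_evidence,
    filter_candidates,
    merge_discordant,
    render_report,
    summarize_candidate,
)
from attrace.detect import DiscordantCandidate
from attrace.realign import AttQuad, JunctionEvidence, SegmentAlignment
from attrace.sam_io import AlignmentRecord

from table_fixtures import ALL_ROWS


def make_evidence(quad_pts, jtype="attB", ref="chr", read_id="r"):
    l1, l2, r1, r2 = quad_pts
    quad = AttQuad(ref, l1, l2, r1, r2)
    ov = quad.att_len
    left = SegmentAlignment(1, 60 + ov, l1 - 60, l2, ref)
    right = SegmentAlignment(61, 120 + ov, r1, r2 + 60, ref)
    if jtype == "attP":
        left = SegmentAlignment(1, 60 + ov, r1 - 60, r2, ref)
        right = SegmentAlignment(61, 120 + ov, l1, l2 + 60, ref)
    return JunctionEvidence(read_id, jtype, left, right, ov, quad)


def make_drp_pair(name, fwd_pos, rev_pos, ref="chr", read_len=150):
    recs = []
    for flag, pos in ((97, fwd_pos), (145, rev_pos)):
        rec = AlignmentRecord(
            query_name=name, flag_raw=flag, ref_name=ref, pos=pos, mapq=60,
            cigar=(("M", read_len),), mate_ref_name=ref,
            mate_pos=rev_pos if flag == 97 else fwd_pos, tlen=0,
            query_seq="A" * read_len,
        )
        recs.append(DiscordantCandidate(rec, read_len, flag, "chromosome"))
    return recs


QUAD = (10_000, 10_029, 40_000, 40_029)  # size 30000, att 30


class TestClustering:
    def test_identical_quads_form_one_cluster(self):
        evs = [make_evidence(QUAD, read_id=f"r{i}") for i in range(3)]
        clusters = cluster_evidence(evs, tol=2)
        assert len(clusters) == 1
        assert clusters[0].consensus.endpoints() == QUAD
        assert len(clusters[0].members) == 3

    def test_distant_attR_split_into_two_clusters(self):
        evs = [
            make_evidence((100, 110, 5000, 5010)),
            make_evidence((100, 110, 5000, 5010)),
            make_evidence((100, 110, 9000, 9010)),
        ]
        assert len(cluster_evidence(evs, tol=2)) == 2

    def test_near_quads_merge_with_modal_consensus(self):
        # one-base-longer core seen by a minority of reads
        shifted = (QUAD[0] - 1, QUAD[1], QUAD[2] - 1, QUAD[3])
        evs = [make_evidence(QUAD), make_evidence(QUAD), make_evidence(shifted)]
        clusters = cluster_evidence(evs, tol=2)
        assert len(clusters) == 1
        assert clusters[0].consensus.endpoints() == QUAD  # mode of 2 vs 1

    def test_modal_ties_take_smaller_coordinate(self):
        shifted = (QUAD[0] - 1, QUAD[1], QUAD[2] - 1, QUAD[3])
        clusters = cluster_evidence([make_evidence(QUAD), make_evidence(shifted)], tol=2)
        assert clusters[0].consensus.endpoints() == (
            QUAD[0] - 1, QUAD[1], QUAD[2] - 1, QUAD[3]
        )

    def test_partition_matches_bounded_single_link_oracle(self):
        """Brute-force oracle: single-link components under the 'within
        tol on every endpoint' relation, with the 2*tol diameter bound."""
        offsets = [0, 1, 2, 7, 8, 40]
        evs = [
            make_evidence((QUAD[0] + o, QUAD[1] + o, QUAD[2] + o, QUAD[3] + o),
                          read_id=f"r{i}")
            for i, o in enumerate(offsets)
        ]
        clusters = cluster_evidence(evs, tol=2)
        # disjoint cover
        ids = sorted(m.read_id for cl in clusters for m in cl.members)
        assert ids == sorted(e.read_id for e in evs)
        for cl in clusters:
            pts = [m.quad.endpoints() for m in cl.members]
            for a, b in itertools.combinations(pts, 2):
                assert all(abs(x - y) <= 4 for x, y in zip(a, b))
            if len(pts) > 1:
                for a in pts:
                    assert any(
                        all(abs(x - y) <= 2 for x, y in zip(a, b))
                        for b in pts if b is not a
                    )
        # offsets 0,1,2 chain together; 7,8 together; 40 alone
        assert sorted(len(c.members) for c in clusters) == [1, 2, 3]


class TestMergeDiscordant:
    def _cluster(self):
        return cluster_evidence([make_evidence(QUAD)], tol=2)

    def test_outward_flanking_pair_supports_attB(self):
        clusters = self._cluster()
        drps = make_drp_pair("d1", QUAD[0] - 300 - 149, QUAD[3] + 250)
        clusters, dropped = merge_discordant(clusters, [d for p in [drps] for d in p], 1000)
        assert clusters[0].drp_attB == 1
        assert clusters[0].drp_attP == 0
        assert dropped == 0

    def test_inward_everted_pair_supports_attP(self):
        clusters = self._cluster()
        # forward read just inside attR, reverse read just inside attL
        drps = make_drp_pair("d2", QUAD[2] - 300, QUAD[0] + 5)
        clusters, dropped = merge_discordant(clusters, drps, 1000)
        assert clusters[0].drp_attP == 1
        assert dropped == 0

    def test_unrelated_pair_dropped(self):
        clusters = self._cluster()
        drps = make_drp_pair("d3", 80_000, 95_000)
        clusters, dropped = merge_discordant(clusters, drps, 1000)
        assert clusters[0].drp_attB == clusters[0].drp_attP == 0
        assert dropped == 1

    def test_pair_assigned_to_tightest_cluster_only_once(self):
        evs = [
            make_evidence(QUAD),
            make_evidence((QUAD[0] - 400, QUAD[1] - 400, QUAD[2] + 400, QUAD[3] + 400)),
        ]
        clusters = cluster_evidence(evs, tol=2)
        drps = make_drp_pair("d4", QUAD[0] - 200 - 149, QUAD[3] + 180)
        clusters, _ = merge_discordant(clusters, drps, 1000)
        totals = [c.drp_attB + c.drp_attP for c in clusters]
        assert sorted(totals) == [0, 1]
        tight = next(c for c in clusters if c.consensus.endpoints() == QUAD)
        assert tight.drp_attB == 1


class TestFiltering:
    def _cluster_with(self, quad_pts, n_attB, n_attP):
        evs = [make_evidence(quad_pts, "attB", read_id=f"b{i}") for i in range(n_attB)]
        evs += [make_evidence(quad_pts, "attP", read_id=f"p{i}") for i in range(n_attP)]
        return cluster_evidence(evs, tol=2)

    def test_published_geometry_retained(self):
        clusters = self._cluster_with((785288, 785336, 797699, 797747), 2, 1)
        out = filter_candidates(clusters)
        assert len(out) == 1
        assert out[0].size == 12411 and out[0].att_len == 49
        assert out[0].name == "P1"

    def test_size_bounds_are_exclusive(self):
        small = self._cluster_with((1000, 1019, 5800, 5819), 2, 2)   # size 4800
        assert filter_candidates(small) == []
        exactly_min = self._cluster_with((1000, 1019, 6000, 6019), 2, 2)  # size 5000
        assert filter_candidates(exactly_min) == []

    def test_att_length_bound_is_exclusive(self):
        two_bp = self._cluster_with((1000, 1001, 40_000, 40_001), 2, 2)
        assert filter_candidates(two_bp) == []
        three_bp = self._cluster_with((1000, 1002, 40_000, 40_002), 2, 2)
        assert len(filter_candidates(three_bp)) == 1

    def test_both_event_classes_required_by_default(self):
        only_attB = self._cluster_with(QUAD, 3, 0)
        assert filter_candidates(only_attB) == []
        relaxed = FilterConfig(min_attP_events=0)
        assert len(filter_candidates(only_attB, relaxed)) == 1

    def test_filtering_is_monotone_in_every_bound(self):
        clusters = self._cluster_with(QUAD, 1, 1)
        base = FilterConfig()
        kept = {c.ref_name + str(c.attL_start) for c in filter_candidates(clusters, base)}
        looser = [
            FilterConfig(min_att_len=0),
            FilterConfig(min_size=1000),
            FilterConfig(max_size=10**6),
            FilterConfig(min_attB_events=0),
            FilterConfig(min_attP_events=0),
        ]
        for cfg in looser:
            now = {c.ref_name + str(c.attL_start) for c in filter_candidates(clusters, cfg)}
            assert kept <= now

    def test_candidates_sorted_and_named(self):
        evs = [
            make_evidence((50_000, 50_019, 80_000, 80_019), "attB", read_id="a"),
            make_evidence((50_000, 50_019, 80_000, 80_019), "attP", read_id="b"),
            make_evidence((1000, 1019, 30_000, 30_019), "attB", read_id="c"),
            make_evidence((1000, 1019, 30_000, 30_019), "attP", read_id="d"),
        ]
        out = filter_candidates(cluster_evidence(evs, tol=2))
        assert [c.name for c in out] == ["P1", "P2"]
        assert out[0].attL_start == 1000


class TestSummary:
    @pytest.mark.parametrize(
        "name, ref, l1, l2, r1, r2, size, att_len", ALL_ROWS,
        ids=[r[0] for r in ALL_ROWS],
    )
    def test_size_and_att_length_identities(self, name, ref, l1, l2, r1, r2, size, att_len):
        """Every published row satisfies size = attR_start - attL_start
        and att_len = attL span = attR span."""
        cluster = CandidateCluster(consensus=AttQuad(ref, l1, l2, r1, r2))
        cand = summarize_candidate(cluster)
        assert cand.size == size
        assert cand.att_len == att_len
        assert r2 - r1 + 1 == att_len

    def test_evidence_rendering_mentions_both_pieces(self):
        ev = make_evidence(QUAD)
        cluster = cluster_evidence([ev], tol=2)[0]
        cand = summarize_candidate(cluster)
        assert "ov=30" in cand.evidence_alignments
        assert "q[1-" in cand.evidence_alignments

    def test_report_layout(self):
        clusters = cluster_evidence(
            [make_evidence(QUAD, "attB"), make_evidence(QUAD, "attP")], tol=2
        )
        df = render_report(filter_candidates(clusters))
        assert list(df.columns) == [
            "prophage", "contig", "attL_start", "attL_end", "attR_start",
            "attR_end", "size", "att_length", "SR_attB", "SR_attP",
            "DRP_attB", "DRP_attP",
        ]
        assert df.iloc[0]["size"] == 30_000


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_size=10_000, max_size=5_000)
    with pytest.raises(ValueError):
        FilterConfig(min_att_len=-1)
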