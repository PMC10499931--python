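"""Tests for SV breakpoint matching, merging, evidence rules and rescue."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consevo import (
    Breakend,
    BreakpointPair,
    apply_sv_retention,
    filter_size,
    filter_sv_pon_germline,
    match_pairs,
    merge_svs,
    rescue_svs,
)
from consevo.sv import ConsensusSV, reciprocal_overlap


def deletion(pos1, pos2, chrom="chr1", caller="manta", t_split=0, n_split=0):
    return BreakpointPair(a=Breakend(chrom, pos1, "+"), b=Breakend(chrom, pos2, "-"),
                          sample="S1", caller=caller, t_split=t_split, n_split=n_split)


def translocation(pos1=50_000, pos2=80_000, o1="+", o2="-", caller="manta"):
    return BreakpointPair(a=Breakend("chr1", pos1, o1), b=Breakend("chr2", pos2, o2),
                          sample="S1", caller=caller)


class TestMatchPairs:
    def test_identical_pairs_match(self):
        p = deletion(10_000, 110_000)
        assert match_pairs(p, p)

    def test_large_deletion_shifted_within_slop_matches(self):
        p = deletion(10_000, 110_000)
        q = deletion(10_299, 110_299)
        # reciprocal overlap ~99.7%, slop satisfied at both ends
        assert match_pairs(p, q)

    def test_distant_same_size_deletions_do_not_match(self):
        assert not match_pairs(deletion(10_000, 11_000), deletion(13_000, 14_000))

    def test_orientation_mismatch_blocks_match(self):
        p = translocation(o1="+")
        q = translocation(o1="-")
        assert not match_pairs(p, q)

    @pytest.mark.parametrize("shift,expected", [(299, True), (300, True), (301, False)])
    def test_translocation_slop_boundary(self, shift, expected):
        p = translocation()
        q = translocation(pos1=50_000 + shift, pos2=80_000 + shift)
        assert match_pairs(p, q) is expected
        # brute-force check of the rule itself
        assert expected == (shift <= 300)

    @pytest.mark.parametrize("q_span,expected", [(490, False), (510, True)])
    def test_reciprocal_overlap_boundary(self, q_span, expected):
        # p spans 1 kb; q nested with both breakends within slop
        p = deletion(10_000, 11_000)
        q = deletion(10_300, 10_300 + q_span)
        ro = reciprocal_overlap(10_000, 11_000, 10_300, 10_300 + q_span)
        assert ro == pytest.approx(q_span / 1000)
        assert match_pairs(p, q) is expected
        assert expected == (ro >= 0.5)

    def test_intra_vs_inter_never_match(self):
        assert not match_pairs(deletion(10_000, 110_000),
                               translocation(pos1=10_000, pos2=110_000))

    @settings(deadline=None, max_examples=200)
    @given(
        p1=st.integers(10_000, 50_000), s1=st.integers(600, 50_000),
        p2=st.integers(10_000, 50_000), s2=st.integers(600, 50_000),
    )
    def test_symmetry(self, p1, s1, p2, s2):
        a = deletion(p1, p1 + s1)
        b = deletion(p2, p2 + s2)
        assert match_pairs(a, b) == match_pairs(b, a)


class TestFilterSize:
    @pytest.mark.parametrize("span,kept", [(499, False), (500, True), (501, True)])
    def test_span_boundary(self, span, kept):
        pairs = filter_size([deletion(10_000, 10_000 + span)])
        assert bool(pairs) is kept

    def test_translocations_always_kept(self):
        assert filter_size([translocation()])


class TestMergeSvs:
    def test_jittered_replicates_form_one_cluster(self):
        per_caller = {
            "manta": [deletion(10_000, 110_000, caller="manta")],
            "lumpy": [deletion(10_120, 109_900, caller="lumpy")],
        }
        out = merge_svs(per_caller)
        assert len(out) == 1
        assert out[0].callers == {"manta", "lumpy"}
        # representative is the per-breakend median (lower-middle for ties)
        assert out[0].a.pos == 10_000 and out[0].b.pos == 109_900

    def test_distant_events_stay_separate(self):
        per_caller = {"manta": [deletion(10_000, 110_000),
                                deletion(300_000, 400_000)]}
        assert len(merge_svs(per_caller)) == 2

    def test_single_caller_cluster_of_one(self):
        out = merge_svs({"lumpy": [deletion(10_000, 110_000, caller="lumpy")]})
        assert len(out) == 1 and out[0].callers == {"lumpy"}

    def test_order_invariance(self):
        pairs = [deletion(10_000 + 50 * i, 110_000 + 50 * i, caller=c)
                 for i, c in enumerate(["manta", "lumpy", "svaba"])]
        a = merge_svs({"manta": [pairs[0]], "lumpy": [pairs[1]], "svaba": [pairs[2]]})
        b = merge_svs({"svaba": [pairs[2]], "manta": [pairs[0]], "lumpy": [pairs[1]]})
        assert [(c.a.pos, c.b.pos, c.callers) for c in a] == \
               [(c.a.pos, c.b.pos, c.callers) for c in b]


def consensus(callers, t_split=0, n_split=0, pos1=10_000, pos2=110_000):
    return ConsensusSV(a=Breakend("chr1", pos1, "+"), b=Breakend("chr1", pos2, "-"),
                       callers=frozenset(callers), t_split=t_split, n_split=n_split)


class TestPonGermlineFilters:
    @pytest.mark.parametrize("n_indiv,flagged", [(2, True), (1, False)])
    def test_pon_individual_threshold(self, n_indiv, flagged):
        c = consensus({"manta", "lumpy"})
        pon = [(deletion(10_050, 110_050), n_indiv)]
        filter_sv_pon_germline([c], pon, [])
        assert bool(c.flags) is flagged

    def test_germline_db_match_flags(self):
        c = consensus({"manta", "lumpy"})
        db = [BreakpointPair(a=Breakend("chr1", 10_100, "."),
                             b=Breakend("chr1", 110_100, "."))]
        filter_sv_pon_germline([c], [], db)
        assert "GERMLINE_DB" in c.flags


class TestSvRetention:
    def test_two_callers_retained(self):
        c = consensus({"manta", "svaba"})
        apply_sv_retention([c], [])
        assert c.retained

    def test_manta_only_with_nearby_changepoint_retained(self):
        c = consensus({"manta"})
        apply_sv_retention([c], [("chr1", 10_900)])  # 900 bp from breakend A
        assert c.retained

    def test_lumpy_only_with_tumor_split_reads_retained(self):
        c = consensus({"lumpy"}, t_split=3, n_split=0)
        apply_sv_retention([c], [])
        assert c.retained

    def test_split_reads_in_normal_block_evidence(self):
        c = consensus({"lumpy"}, t_split=5, n_split=1)
        apply_sv_retention([c], [])
        assert not c.retained

    def test_svaba_only_without_evidence_dropped(self):
        c = consensus({"svaba"}, t_split=10)
        apply_sv_retention([c], [("chr1", 10_900)])
        assert not c.retained

    def test_flagged_sv_never_retained(self):
        c = consensus({"manta", "lumpy"})
        c.flags.add("PON")
        apply_sv_retention([c], [])
        assert not c.retained


class TestSvRescue:
    def retained_sv(self):
        c = consensus({"manta", "lumpy"})
        c.retained = True
        return c

    @pytest.mark.parametrize("reads,rescued", [(1, True), (0, False)])
    def test_read_support_threshold(self, reads, rescued):
        support = {"S1": [(deletion(10_000, 110_000), reads)], "S2": []}
        out = rescue_svs({"S1": [], "S2": [self.retained_sv()]}, support)
        assert bool([c for c in out["S1"] if c.rescued]) is rescued

    def test_single_sample_patient_unchanged(self):
        c = self.retained_sv()
        out = rescue_svs({"S1": [c]}, {})
        assert out == {"S1": [c]}
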