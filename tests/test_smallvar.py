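"""Unit and property tests for small-variant consensus, filtering and rescue."""

import random

import pytest

from consevo import (
    ConsensusVariant,
    Pileup,
    VariantCall,
    apply_retention,
    assign_allele_counts,
    filter_pon,
    filter_population_af,
    filter_vaf_depth,
    merge_small_variants,
    normalize_key,
    rescue_multisample,
    split_mnvs,
)
from consevo.smallvar import (
    FLAG_HIGH_NORMAL_VAF,
    FLAG_LOW_TUMOR_VAF,
    FLAG_NORMAL_GE_TUMOR,
    FLAG_PON,
    FLAG_POP_AF,
)


def call(chrom="chr1", pos=100, ref="A", alt="G", caller="mutect2", **kw):
    kw.setdefault("t_alt", 10)
    kw.setdefault("t_ref", 30)
    kw.setdefault("n_alt", 0)
    kw.setdefault("n_ref", 40)
    return VariantCall(sample="S1", chrom=chrom, pos=pos, ref=ref, alt=alt,
                       caller=caller, **kw)


class TestNormalizeKey:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            (("chr1", 100, "A", "G"), ("chr1", 100, "A", "G")),
            (("chr1", 100, "ATT", "GTT"), ("chr1", 100, "A", "G")),
            (("chr1", 100, "TAC", "TGC"), ("chr1", 101, "A", "G")),
            (("chr1", 100, "A", "AGT"), ("chr1", 100, "A", "AGT")),
            (("chr1", 100, "ACT", "A"), ("chr1", 100, "ACT", "A")),
        ],
    )
    def test_trimming(self, raw, expected):
        assert normalize_key(*raw) == expected


class TestSplitMnvs:
    def test_dinucleotide_splits_to_consecutive_snvs(self):
        out = split_mnvs([call(ref="AC", alt="GT")])
        assert [(c.pos, c.ref, c.alt) for c in out] == [(100, "A", "G"), (101, "C", "T")]
        assert len({c.parent for c in out}) == 1

    def test_non_mnvs_pass_through_unchanged(self):
        calls = [call(), call(pos=200, ref="A", alt="AT")]
        assert split_mnvs(calls) == calls

    @pytest.mark.parametrize("length", [2, 3])
    def test_split_count_matches_mnv_length(self, length):
        ref = "ACG"[:length]
        alt = "GTA"[:length]
        out = split_mnvs([call(ref=ref, alt=alt)])
        assert len(out) == length
        assert len({c.parent for c in out}) == 1


class TestMergeSmallVariants:
    def test_uniform_support_refuses_mnv(self):
        per_caller = {
            "mutect2": split_mnvs([call(ref="AC", alt="GT", caller="mutect2")]),
            "lancet": split_mnvs([call(ref="AC", alt="GT", caller="lancet")]),
        }
        out = merge_small_variants(per_caller)
        assert len(out) == 1
        assert (out[0].ref, out[0].alt) == ("AC", "GT")
        assert out[0].callers == {"mutect2", "lancet"}

    def test_uneven_support_keeps_individual_snvs(self):
        # strelka2 reports only the second constituent SNV
        per_caller = {
            "mutect2": split_mnvs([call(ref="AC", alt="GT", caller="mutect2")]),
            "strelka2": [call(pos=101, ref="C", alt="T", caller="strelka2")],
        }
        out = merge_small_variants(per_caller)
        assert sorted((v.pos, v.ref, v.alt) for v in out) == [
            (100, "A", "G"), (101, "C", "T")]
        supports = {v.pos: v.callers for v in out}
        assert supports[100] == {"mutect2"}
        assert supports[101] == {"mutect2", "strelka2"}

    def test_single_caller_single_snv(self):
        out = merge_small_variants({"mutect2": [call()]})
        assert len(out) == 1 and out[0].callers == {"mutect2"}

    def test_delins_not_fused_with_adjacent_records(self):
        per_caller = {
            "lancet": [call(ref="AC", alt="GTT", caller="lancet"),
                       call(pos=105, ref="A", alt="G", caller="lancet")],
        }
        out = merge_small_variants(per_caller)
        assert sorted(v.var_class for v in out) == ["DELINS", "SNV"]

    def test_order_invariance(self):
        calls = [call(pos=p, ref="A", alt="G", caller=c)
                 for p in (100, 200, 300) for c in ("mutect2", "strelka2")]
        shuffled = list(calls)
        random.Random(7).shuffle(shuffled)

        def group(cs):
            d = {}
            for c in cs:
                d.setdefault(c.caller, []).append(c)
            return d

        a = merge_small_variants(group(calls))
        b = merge_small_variants(group(shuffled))
        assert [(v.key, v.callers) for v in a] == [(v.key, v.callers) for v in b]


class TestAssignAlleleCounts:
    def make_pileup(self):
        pile = Pileup()
        pile.add("S1", "tumor", "chr1", 100, "A", 15, 20)
        pile.add("S1", "tumor", "chr1", 100, "G", 5, 20)
        pile.add("S1", "normal", "chr1", 100, "A", 30, 30)
        pile.add("S1", "normal", "chr1", 100, "G", 0, 30)
        return pile

    def test_snv_counts_from_pileup(self):
        v = ConsensusVariant(chrom="chr1", pos=100, ref="A", alt="G",
                             callers=frozenset({"mutect2"}))
        assign_allele_counts([v], self.make_pileup(), "S1")
        assert (v.t_alt, v.t_ref) == (5, 15)
        assert v.tumor_vaf == pytest.approx(0.25)
        assert v.counts_source == "pileup"

    def test_long_indel_prefers_strelka_counts(self):
        v = ConsensusVariant(
            chrom="chr1", pos=100, ref="A" + "T" * 12, alt="A",
            callers=frozenset({"strelka2", "lancet"}),
            caller_counts={"strelka2": (8, 40, 0, 30), "lancet": (9, 41, 1, 29)},
        )
        assign_allele_counts([v], Pileup(), "S1")
        assert (v.t_alt, v.t_ref) == (8, 40)
        assert v.counts_source == "strelka2"

    def test_incomplete_preferred_caller_skipped(self):
        v = ConsensusVariant(
            chrom="chr1", pos=100, ref="A" + "T" * 12, alt="A",
            callers=frozenset({"strelka2", "mutect2"}),
            caller_counts={"strelka2": (8, None, 0, 30), "mutect2": (7, 44, 0, 31)},
        )
        assign_allele_counts([v], Pileup(), "S1")
        assert v.counts_source == "mutect2"

    def test_svaba_only_long_indel_has_no_vaf(self):
        v = ConsensusVariant(
            chrom="chr1", pos=100, ref="A" + "T" * 14, alt="A",
            callers=frozenset({"svaba"}),
            caller_counts={"svaba": (12, None, 0, None)},
        )
        assign_allele_counts([v], Pileup(), "S1")
        assert v.t_alt is None and v.tumor_vaf is None


class TestFilters:
    def variant(self, **kw):
        defaults = dict(chrom="chr1", pos=100, ref="A", alt="G",
                        callers=frozenset({"mutect2", "strelka2"}),
                        t_alt=10, t_ref=30, n_alt=0, n_ref=40)
        defaults.update(kw)
        return ConsensusVariant(**defaults)

    @pytest.mark.parametrize("count,flagged", [(2, True), (3, True), (1, False), (0, False)])
    def test_pon_threshold(self, count, flagged):
        v = self.variant()
        pon = {v.key: count} if count else {}
        filter_pon([v], pon)
        assert (FLAG_PON in v.flags) is flagged

    @pytest.mark.parametrize("afs,flagged", [
        ({"1000g": 0.01, "gnomad": 0.0}, True),
        ({"1000g": 0.0099, "gnomad": 0.0099}, False),
        (None, False),
    ])
    def test_population_af_threshold(self, afs, flagged):
        v = self.variant()
        table = {v.key: afs} if afs else {}
        filter_population_af([v], table)
        assert (FLAG_POP_AF in v.flags) is flagged

    def test_low_tumor_vaf_flag(self):
        v = self.variant(t_alt=1, t_ref=19999)
        filter_vaf_depth([v])
        assert FLAG_LOW_TUMOR_VAF in v.flags

    def test_high_normal_vaf_flag(self):
        v = self.variant(n_alt=10, n_ref=30)
        filter_vaf_depth([v])
        assert FLAG_HIGH_NORMAL_VAF in v.flags

    def test_normal_above_tumor_flag(self):
        v = self.variant(t_alt=2, t_ref=38, n_alt=4, n_ref=36)
        filter_vaf_depth([v])
        assert FLAG_NORMAL_GE_TUMOR in v.flags

    def test_absent_counts_exempt_from_vaf_depth(self):
        v = self.variant(t_alt=None, t_ref=None, n_alt=None, n_ref=None)
        filter_vaf_depth([v])
        assert not v.flags


class TestRetention:
    def variant(self, callers, **kw):
        defaults = dict(chrom="chr1", pos=100, ref="A", alt="G",
                        callers=frozenset(callers))
        defaults.update(kw)
        return ConsensusVariant(**defaults)

    def test_two_callers_retained(self):
        v = self.variant({"mutect2", "strelka2"})
        apply_retention([v])
        assert v.retained

    def test_single_caller_with_validation_retained(self):
        v = self.variant({"mutect2"})
        apply_retention([v], lancet_validation={v.key})
        assert v.retained

    def test_single_caller_unvalidated_dropped(self):
        v = self.variant({"mutect2"})
        apply_retention([v])
        assert not v.retained

    def test_flagged_variant_never_retained(self):
        v = self.variant({"mutect2", "strelka2"})
        v.flags.add(FLAG_PON)
        apply_retention([v])
        assert not v.retained


class TestRescue:
    def setup_pileup(self, alt_in_primary):
        pile = Pileup()
        for sample in ("S1", "S2"):
            alt = alt_in_primary if sample == "S1" else 20
            pile.add(sample, "tumor", "chr1", 100, "G", alt, 40)
            pile.add(sample, "tumor", "chr1", 100, "A", 40 - alt, 40)
            pile.add(sample, "normal", "chr1", 100, "G", 0, 40)
            pile.add(sample, "normal", "chr1", 100, "A", 40, 40)
        return pile

    def retained_variant(self):
        v = ConsensusVariant(chrom="chr1", pos=100, ref="A", alt="G",
                             callers=frozenset({"mutect2", "strelka2"}),
                             t_alt=20, t_ref=20, n_alt=0, n_ref=40)
        v.retained = True
        return v

    def test_variant_with_read_support_rescued(self):
        out = rescue_multisample({"S1": [], "S2": [self.retained_variant()]},
                                 self.setup_pileup(alt_in_primary=2))
        rescued = [v for v in out["S1"] if v.rescued]
        assert len(rescued) == 1
        assert rescued[0].t_alt == 2 and not rescued[0].retained

    def test_zero_support_not_rescued(self):
        out = rescue_multisample({"S1": [], "S2": [self.retained_variant()]},
                                 self.setup_pileup(alt_in_primary=0))
        assert not [v for v in out["S1"] if v.rescued]

    def test_single_sample_patient_unchanged(self):
        vs = [self.retained_variant()]
        out = rescue_multisample({"S1": vs}, Pileup())
        assert out == {"S1": vs}


class TestMonotonicity:
    def test_each_filter_only_adds_flags(self):
        v = ConsensusVariant(chrom="chr1", pos=100, ref="A", alt="G",
                             callers=frozenset({"mutect2", "strelka2"}),
                             t_alt=0, t_ref=40, n_alt=20, n_ref=20)
        filter_pon([v], {v.key: 5})
        after_pon = set(v.flags)
        filter_vaf_depth([v])
        assert after_pon <= v.flags
        apply_retention([v])
        assert not v.retained
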