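"""Tests for the synthetic cohort generator and its planted truth."""

import numpy as np
import pytest

from consevo import (
    Breakend,
    BreakpointPair,
    CohortConfig,
    ccf,
    generate_cohort,
    generate_sv_jitter,
    match_pairs,
)


def small_config(**kw):
    kw.setdefault("seed", 11)
    kw.setdefault("n_patients", 2)
    return CohortConfig(**kw)


def perfect_config(**kw):
    """Every caller at sensitivity 1, no contamination of any kind."""
    sens = {c: 1.0 for c in ("mutect2", "strelka2", "lancet", "svaba",
                             "manta", "lumpy")}
    kw.setdefault("caller_sensitivity", sens)
    kw.setdefault("pon_contamination_rate", 0.0)
    kw.setdefault("germline_leak_rate", 0.0)
    kw.setdefault("population_af_rate", 0.0)
    kw.setdefault("pon_singleton_rate", 0.0)
    return small_config(**kw)


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(pon_contamination_rate=1.5)

    def test_nonpositive_chromosome_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(genome=(("chr1", 0),))

    def test_overfull_genome_rejected(self):
        cfg = CohortConfig(genome=(("chr1", 20_000),), sex_chrom="none",
                           n_true_snv=500, seed=1)
        with pytest.raises(ValueError):
            generate_cohort(cfg)


class TestDeterminism:
    def test_same_seed_same_files(self, tmp_path):
        for rep in ("a", "b"):
            generate_cohort(small_config(seed=1)).write(tmp_path / rep)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_differ(self):
        a = generate_cohort(small_config(seed=1))
        b = generate_cohort(small_config(seed=2))
        assert not a.truth_small.equals(b.truth_small)


class TestPerfectSensitivity:
    def test_every_truth_variant_called_by_every_eligible_caller(self):
        cohort = generate_cohort(perfect_config())
        truth = cohort.truth_small
        eligible = {"SNV": 3, "MNV": 3, "INDEL": 4, "DELINS": 1}
        for row in truth[truth.present].itertuples():
            n_callers = len(row.callers.split(","))
            assert n_callers == eligible[row.var_class], row


class TestPlantedVafs:
    def test_vaf_ccf_identity_round_trips(self):
        cohort = generate_cohort(small_config())
        truth = cohort.truth_small
        rows = truth[(truth.artifact == "somatic") & truth.present]
        assert len(rows) > 100
        purities = cohort.samples.set_index("sample")["purity"]
        for row in rows.itertuples():
            # re-derive CCF from the planted VAF via the CCF formula
            purity = purities.loc[row.sample]
            value = ccf(row.tumor_vaf, int(row.multiplicity), float(purity),
                        float(row.n_t), float(row.n_n))
            assert value == pytest.approx(row.ccf, abs=1e-9)


class TestTransitionPlanting:
    def test_planted_counts_follow_rounding_rule(self):
        cfg = CohortConfig(
            seed=5, n_patients=1, samples_per_patient=(2, 2),
            shared_fraction=1.0, subclonal_fraction_primary=1.0,
            transition_fraction=0.83, n_true_snv=200, n_true_mnv=0,
            n_true_indel=0, n_true_sv=0,
            pon_contamination_rate=0.0, germline_leak_rate=0.0,
            population_af_rate=0.0,
        )
        truth = generate_cohort(cfg).truth_small
        primary, met = sorted(truth["sample"].unique())
        sub_primary = set(
            truth[(truth["sample"] == primary) & (truth.timing == "subclonal")].vid)
        assert len(sub_primary) == 200
        met_rows = truth[(truth["sample"] == met) & truth.vid.isin(sub_primary)]
        n_clonal = int((met_rows.timing != "subclonal").sum())
        assert n_clonal == 166  # round(0.83 * 200)


class TestSvJitter:
    def base_pair(self, span=100_000):
        return BreakpointPair(a=Breakend("chr1", 50_000, "+"),
                              b=Breakend("chr1", 50_000 + span, "-"),
                              caller="manta")

    def test_zero_jitter_is_identity(self):
        p = self.base_pair()
        assert generate_sv_jitter(p, 0) == p

    def test_jitter_bounded_and_orientation_preserved(self):
        rng = np.random.default_rng(2)
        p = self.base_pair()
        for _ in range(50):
            q = generate_sv_jitter(p, 299, rng)
            assert abs(q.a.pos - p.a.pos) <= 299
            assert abs(q.b.pos - p.b.pos) <= 299
            assert (q.a.orient, q.b.orient) == ("+", "-")

    def test_jitter_within_slop_still_merges(self):
        rng = np.random.default_rng(3)
        p = self.base_pair()
        for _ in range(50):
            assert match_pairs(p, generate_sv_jitter(p, 299, rng))

    def test_jitter_breaking_reciprocal_overlap_fails_merge(self):
        # 500 bp event shifted +290 on both ends keeps slop but drops
        # reciprocal overlap to 42%
        p = self.base_pair(span=500)
        q = BreakpointPair(a=Breakend("chr1", 50_290, "+"),
                           b=Breakend("chr1", 50_790, "-"))
        assert not match_pairs(p, q)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            generate_sv_jitter(self.base_pair(), -1)


class TestTruthInternalConsistency:
    def test_rescued_rows_have_read_support(self):
        truth = generate_cohort(small_config(seed=3)).truth_small
        rescued = truth[truth.expect_rescued]
        assert (rescued.t_alt > 0).all()
        assert (~rescued.expect_retained).all()

    def test_final_implies_retained_or_rescued(self):
        truth = generate_cohort(small_config(seed=3)).truth_small
        assert (truth.expect_final ==
                (truth.expect_retained | truth.expect_rescued)).all()

    def test_artifacts_never_survive(self):
        truth = generate_cohort(small_config(seed=3)).truth_small
        bad = truth[truth.artifact.isin(["pon", "pop_af", "germline_leak"])]
        assert not bad.expect_final.any()
        # every PON/population artifact carries its defining flag
        assert (bad[bad.artifact == "pon"].expect_flags.fillna("")
                .str.contains("PON").all())
        assert (bad[bad.artifact == "pop_af"].expect_flags.fillna("")
                .str.contains("POP_AF").all())
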