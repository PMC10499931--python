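"""Synthetic multi-sample tumor cohort generator with planted ground truth.

Emulates the inputs of a post-calling consensus pipeline for a cohort of
prostate-cancer patients, each with 1-3 tumor samples (a primary and one or
two metastases): per-caller SNV/MNV/indel call sets, per-caller SV breakpoint
pairs with positional jitter, tumor/normal pileup-count tables (the stand-in
for BAM pileups), a panel of normals with per-variant individual counts,
population allele frequencies, a germline-SV database, integer copy-number
segments, purity/ploidy/sex metadata, and a truth table recording, for every
planted record, its caller support, planted VAF/CCF/multiplicity/timing and
the survival expected at each filter stage.

Planted tumor VAFs satisfy the CCF identity
``f = CCF * n * rho / (rho * N_T + N_N * (1 - rho))`` at each locus, so the
clonality stage can recover planted CCFs and timing classes.  All output is
a deterministic function of the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clonality import vaf_from_ccf
from .smallvar import normalize_key
from .sv import Breakend, BreakpointPair

BASES = ("A", "C", "G", "T")

SMALL_CALLERS_BY_CLASS = {
    "SNV": ("mutect2", "strelka2", "lancet"),
    "MNV": ("mutect2", "strelka2", "lancet"),
    "INDEL_SHORT": ("mutect2", "strelka2", "lancet", "svaba"),
    "INDEL_LONG": ("mutect2", "strelka2", "lancet", "svaba"),
    "DELINS": ("lancet",),
}
SV_CALLER_NAMES = ("manta", "lumpy", "svaba")

DEFAULT_SENSITIVITY = {
    "mutect2": 0.85,
    "strelka2": 0.85,
    "lancet": 0.75,
    "svaba": 0.7,
    "manta": 0.85,
    "lumpy": 0.8,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a small multi-sample WGS cohort: tumor coverage near
    90x with matched normals near 45x, purities 0.55-0.95, a mix of diploid
    and aneuploid genomes (including a half-integer ploidy exercising the
    two-state neutral window), 60% of a patient's variants shared across
    its samples, and a primary-to-metastasis subclonal-to-clonal transition
    fraction of 0.83.
    """

    n_patients: int = 4
    samples_per_patient: tuple[int, int] = (1, 3)
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000),
        ("chr2", 4_000_000),
        ("chrX", 3_000_000),
    )
    sex_chrom: str = "chrX"
    n_true_snv: int = 40
    n_true_mnv: int = 4
    n_true_indel: int = 10
    n_true_sv: int = 8
    caller_sensitivity: dict = field(default_factory=lambda: dict(DEFAULT_SENSITIVITY))
    pon_contamination_rate: float = 0.05
    germline_leak_rate: float = 0.05
    population_af_rate: float = 0.03
    pon_singleton_rate: float = 0.03
    purity_range: tuple[float, float] = (0.55, 0.95)
    ploidy_choices: tuple[float, ...] = (2.0, 2.2, 3.5)
    shared_fraction: float = 0.6
    subclonal_fraction_primary: float = 0.4
    transition_fraction: float = 0.83
    subclonal_ccf_range: tuple[float, float] = (0.2, 0.5)
    depth_mean_tumor: float = 90.0
    depth_mean_normal: float = 45.0
    depth_floor: int = 20
    sv_jitter_max: int = 80
    small_sv_rate: float = 0.1
    delins_rate: float = 0.15
    clonal_early_rate: float = 0.3
    min_spacing: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        probs = dict(
            pon_contamination_rate=self.pon_contamination_rate,
            germline_leak_rate=self.germline_leak_rate,
            population_af_rate=self.population_af_rate,
            pon_singleton_rate=self.pon_singleton_rate,
            shared_fraction=self.shared_fraction,
            subclonal_fraction_primary=self.subclonal_fraction_primary,
            transition_fraction=self.transition_fraction,
            small_sv_rate=self.small_sv_rate,
            delins_rate=self.delins_rate,
            clonal_early_rate=self.clonal_early_rate,
        )
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name, p in self.caller_sensitivity.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"caller_sensitivity[{name}] must be in [0, 1]")
        for chrom, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} must have positive length")
        lo, hi = self.samples_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_patient must be 1 <= lo <= hi")
        plo, phi = self.purity_range
        if not (0 < plo <= phi <= 1):
            raise ValueError("purity_range must lie in (0, 1]")
        if any(p <= 0 for p in self.ploidy_choices):
            raise ValueError("ploidy choices must be positive")
        if self.sv_jitter_max < 0:
            raise ValueError("sv_jitter_max must be >= 0")
        clo, chi = self.subclonal_ccf_range
        if not (0 < clo <= chi < 0.9):
            raise ValueError("subclonal_ccf_range must lie in (0, 0.9)")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.genome if c != self.sex_chrom)


@dataclass
class Cohort:
    """All generated tables, plus the truth tables, as DataFrames."""

    config: CohortConfig
    samples: pd.DataFrame
    small_calls: pd.DataFrame
    pileups: pd.DataFrame
    pon_snv: pd.DataFrame
    population_af: pd.DataFrame
    lancet_validation: pd.DataFrame
    manta_smallsv: pd.DataFrame
    segments: pd.DataFrame
    sv_calls: pd.DataFrame
    pon_sv: pd.DataFrame
    germline_sv: pd.DataFrame
    sv_support: pd.DataFrame
    truth_small: pd.DataFrame
    truth_sv: pd.DataFrame
    truth_fga: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write the cohort to a directory of plain-text files.

        Per-caller small-variant calls go to minimal VCFs (1-based), SV
        calls and SV databases to BEDPE (0-based half-open breakend
        intervals), everything else to TSV.  Output is byte-deterministic.
        """
        from .io import write_caller_vcf, write_bedpe  # avoid cycle at import

        outdir = Path(outdir)
        (outdir / "calls").mkdir(parents=True, exist_ok=True)
        (outdir / "sv_calls").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)

        cfg = asdict(self.config)
        # YAML-friendly plain types
        cfg["genome"] = [[c, int(n)] for c, n in cfg["genome"]]
        for k, v in list(cfg.items()):
            if isinstance(v, tuple):
                cfg[k] = list(v)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)
        )

        def tsv(df: pd.DataFrame, name: str) -> None:
            df.to_csv(outdir / name, sep="\t", index=False, float_format="%.10g")

        tsv(self.samples, "samples.tsv")
        tsv(self.pileups, "pileups.tsv")
        tsv(self.pon_snv, "pon_snv.tsv")
        tsv(self.population_af, "population_af.tsv")
        tsv(self.lancet_validation, "lancet_validation.tsv")
        tsv(self.manta_smallsv, "manta_smallsv.tsv")
        tsv(self.segments, "segments.tsv")
        tsv(self.sv_support, "sv_support.tsv")
        tsv(self.truth_small, "truth/truth_smallvar.tsv")
        tsv(self.truth_sv, "truth/truth_sv.tsv")
        tsv(self.truth_fga, "truth/truth_fga.tsv")

        contigs = list(self.config.genome)
        for (sample, caller), group in sorted(
            self.small_calls.groupby(["sample", "caller"], sort=True)
        ):
            write_caller_vcf(group, outdir / "calls" / f"{sample}.{caller}.vcf", contigs)
        for (sample, caller), group in sorted(
            self.sv_calls.groupby(["sample", "caller"], sort=True)
        ):
            write_bedpe(group, outdir / "sv_calls" / f"{sample}.{caller}.bedpe")
        write_bedpe(self.pon_sv, outdir / "pon_sv.bedpe", extra=["n_individuals"])
        write_bedpe(self.germline_sv, outdir / "germline_sv.bedpe")


# ---------------------------------------------------------------------------
# allele drawing helpers
# ---------------------------------------------------------------------------

def _draw_base(rng: np.random.Generator, exclude: str | None = None) -> str:
    pool = [b for b in BASES if b != exclude]
    return pool[int(rng.integers(len(pool)))]


def _draw_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[int(i)] for i in rng.integers(0, 4, size=length))


def _draw_alleles(rng: np.random.Generator, kind: str, delins_rate: float) -> tuple[str, str, str]:
    """Return (ref, alt, class_key) with no shared prefix/suffix bases."""
    if kind == "snv":
        ref = _draw_base(rng)
        return ref, _draw_base(rng, exclude=ref), "SNV"
    if kind == "mnv":
        length = int(rng.integers(2, 4))
        ref = _draw_seq(rng, length)
        alt = "".join(_draw_base(rng, exclude=b) for b in ref)
        return ref, alt, "MNV"
    # indel family
    if rng.random() < delins_rate:
        a = int(rng.integers(2, 5))
        b = int(rng.integers(2, 5))
        while b == a:
            b = int(rng.integers(2, 5))
        ref = _draw_seq(rng, a)
        alt = _draw_base(rng, exclude=ref[0]) + _draw_seq(rng, b - 2) + _draw_base(
            rng, exclude=ref[-1]
        ) if b >= 2 else _draw_base(rng, exclude=ref[0])
        return ref, alt, "DELINS"
    length = int(rng.choice([1, 2, 3, 4, 5, 6, 8, 12, 15],
                            p=[0.2, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05, 0.08, 0.07]))
    anchor = _draw_base(rng)
    seq = _draw_seq(rng, length)
    if rng.random() < 0.5:  # insertion
        return anchor, anchor + seq, "INDEL_LONG" if length >= 10 else "INDEL_SHORT"
    return anchor + seq, anchor, "INDEL_LONG" if length >= 10 else "INDEL_SHORT"


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:  # noqa: C901 - one long planting pass
    rng = np.random.default_rng(config.seed)
    genome = dict(config.genome)

    # ---- patients, samples, purity/ploidy/sex -------------------------
    sample_rows = []
    patients: list[dict] = []
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        lo, hi = config.samples_per_patient
        n_samples = int(rng.integers(lo, hi + 1))
        sex = "male" if rng.random() < 0.8 else "female"
        samples = []
        for s in range(n_samples):
            sample = f"{patient}_S{s + 1}"
            site = "prostate" if s == 0 else ("brain" if s == 1 else "nonbrain")
            purity = float(rng.uniform(*config.purity_range))
            ploidy = float(rng.choice(config.ploidy_choices))
            samples.append(dict(sample=sample, patient=patient, purity=purity,
                                ploidy=ploidy, sex=sex, site_class=site))
            sample_rows.append(samples[-1])
        patients.append(dict(patient=patient, sex=sex, samples=samples))

    # ---- copy segments per sample --------------------------------------
    # Per-patient segment boundaries (so shared variants sit on comparable
    # loci); per-sample integer CNs drawn around the sample's neutral state.
    seg_rows = []
    fga_rows = []
    boundaries_by_patient: dict[str, dict[str, list[int]]] = {}
    seg_lookup: dict[str, list[tuple[str, int, int, int, int, int]]] = {}
    for pat in patients:
        bounds: dict[str, list[int]] = {}
        for chrom, length in config.genome:
            k = 3
            inner = sorted(
                int(b)
                for b in rng.choice(
                    np.arange(length // 8, length - length // 8, 10_000),
                    size=k, replace=False,
                )
            )
            bounds[chrom] = [0] + inner + [length]
        boundaries_by_patient[pat["patient"]] = bounds

        for smp in pat["samples"]:
            ploidy = smp["ploidy"]
            frac = round(ploidy - math.floor(ploidy), 9)
            if 0.4 <= frac <= 0.6:
                neutral = {math.floor(ploidy), math.ceil(ploidy)}
            else:
                neutral = {int(math.floor(ploidy + 0.5))}
            lo_n, hi_n = min(neutral), max(neutral)
            altered_choices = sorted(
                {max(1, lo_n - 1), hi_n + 1, hi_n + 2, int(math.floor(2 * ploidy)) + 1}
                - neutral
            )
            altered_frac = float(rng.uniform(0.15, 0.45))
            covered = altered = 0
            segs: list[tuple[str, int, int, int, int, int]] = []
            for chrom, length in config.genome:
                male_x = chrom == config.sex_chrom and smp["sex"] == "male"
                edges = bounds[chrom]
                for start, end in zip(edges, edges[1:]):
                    if male_x:
                        cn = 1 if rng.random() > altered_frac else 2
                    elif rng.random() < altered_frac:
                        cn = int(rng.choice(altered_choices))
                    else:
                        cn = int(rng.choice(sorted(neutral)))
                    minor = cn // 2
                    major = cn - minor
                    segs.append((chrom, start, end, cn, major, minor))
                    seg_rows.append(dict(sample=smp["sample"], chrom=chrom,
                                         start=start, end=end, cn=cn,
                                         major_cn=major, minor_cn=minor))
                    if chrom != config.sex_chrom:
                        covered += end - start
                        if cn not in neutral:
                            altered += end - start
            seg_lookup[smp["sample"]] = segs
            fga_rows.append(dict(sample=smp["sample"], fga=altered / covered))

    def locus_cn(sample: str, chrom: str, pos: int) -> tuple[int, int]:
        for c, start, end, cn, major, _minor in seg_lookup[sample]:
            if c == chrom and start < pos <= end:
                return cn, major
        raise KeyError(f"no segment covers {chrom}:{pos} in {sample}")

    # ---- small-variant locus allocation --------------------------------
    per_class = {"snv": config.n_true_snv, "mnv": config.n_true_mnv,
                 "indel": config.n_true_indel}
    plan: list[dict] = []  # one entry per patient-level variant
    for pat in patients:
        n_samples = len(pat["samples"])
        for kind, n in per_class.items():
            n_shared = int(round(config.shared_fraction * n)) if n_samples > 1 else 0
            n_private = n - n_shared
            for _ in range(n_shared):
                plan.append(dict(patient=pat["patient"], kind=kind, scope="shared"))
            for smp in pat["samples"]:
                for _ in range(n_private):
                    plan.append(dict(patient=pat["patient"], kind=kind,
                                     scope=smp["sample"]))
    needed = len(plan)

    slots = {chrom: max(length // config.min_spacing - 2, 0)
             for chrom, length in config.genome}
    total_slots = sum(slots.values())
    if needed > 0.9 * total_slots:
        raise ValueError(
            f"genome too small: {needed} variant loci requested, "
            f"only {total_slots} spaced slots available"
        )
    weights = np.array([slots[c] for c, _ in config.genome], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(needed, weights)
    # guard against per-chromosome overflow of available slots
    for (chrom, _), cnt in zip(config.genome, counts):
        if cnt > slots[chrom]:
            raise ValueError(f"cannot place {cnt} variants on {chrom} without collision")
    loci: list[tuple[str, int]] = []
    for (chrom, length), cnt in zip(config.genome, counts):
        chosen = rng.choice(slots[chrom], size=int(cnt), replace=False)
        for slot in sorted(int(s) for s in chosen):
            offset = int(rng.integers(1, config.min_spacing - 20))
            loci.append((chrom, slot * config.min_spacing + offset))
    order = rng.permutation(len(loci))
    loci = [loci[i] for i in order]

    # ---- plant small variants ------------------------------------------
    call_rows, pileup_rows, truth_rows = [], [], []
    pon_rows, af_rows, lval_rows, msv_rows = [], [], [], []
    vid_counter = 0

    def artifact_class() -> str:
        r = rng.random()
        if r < config.pon_contamination_rate:
            return "pon"
        if r < config.pon_contamination_rate + config.germline_leak_rate:
            return "germline_leak"
        if (r < config.pon_contamination_rate + config.germline_leak_rate
                + config.population_af_rate):
            return "pop_af"
        return "somatic"

    sens = config.caller_sensitivity

    for entry, (chrom, pos) in zip(plan, loci):
        vid_counter += 1
        vid = f"v{vid_counter:05d}"
        ref, alt, class_key = _draw_alleles(rng, entry["kind"], config.delins_rate)
        chrom_n, pos_n, ref_n, alt_n = normalize_key(chrom, pos, ref, alt)
        pos, ref, alt = pos_n, ref_n, alt_n
        pat = next(p for p in patients if p["patient"] == entry["patient"])
        if entry["scope"] == "shared":
            present_samples = [s["sample"] for s in pat["samples"]]
        else:
            present_samples = [entry["scope"]]
        art = artifact_class()
        eligible = SMALL_CALLERS_BY_CLASS[class_key]
        indel_len = abs(len(ref) - len(alt))
        is_long_indel = class_key == "INDEL_LONG"

        # PON / population AF bookkeeping (patient-level identity)
        pon_count = 0
        if art == "pon":
            pon_count = int(rng.integers(2, 5))
        elif art == "somatic" and rng.random() < config.pon_singleton_rate:
            pon_count = 1
        if pon_count:
            pon_rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 n_individuals=pon_count))
        kg_af = gnomad_af = 0.0
        if art == "pop_af":
            kg_af = float(rng.uniform(0.01, 0.3)) if rng.random() < 0.7 else 0.0
            gnomad_af = float(rng.uniform(0.01, 0.3)) if kg_af == 0.0 or rng.random() < 0.5 else 0.0
            if kg_af == 0.0 and gnomad_af == 0.0:
                gnomad_af = float(rng.uniform(0.01, 0.3))
        elif art == "somatic" and rng.random() < 0.05:
            kg_af = float(rng.uniform(1e-4, 0.009))
        if kg_af or gnomad_af:
            af_rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                kg_af=kg_af, gnomad_af=gnomad_af))

        # primary-sample timing decides shared-variant planting downstream
        primary_subclonal = rng.random() < config.subclonal_fraction_primary
        entry.update(vid=vid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     class_key=class_key, art=art, eligible=eligible,
                     indel_len=indel_len, is_long_indel=is_long_indel,
                     pon_count=pon_count, kg_af=kg_af, gnomad_af=gnomad_af,
                     present_samples=present_samples,
                     primary_subclonal=primary_subclonal)

    # per-patient transition planting for shared variants
    for pat in patients:
        mets = pat["samples"][1:]
        shared_sub = [e for e in plan
                      if e["patient"] == pat["patient"] and e["scope"] == "shared"
                      and e.get("vid") and e["primary_subclonal"] and e["art"] == "somatic"]
        for met in mets:
            k = int(round(config.transition_fraction * len(shared_sub)))
            idx = rng.permutation(len(shared_sub))
            chosen = {shared_sub[int(i)]["vid"] for i in idx[:k]}
            for e in shared_sub:
                e.setdefault("met_clonal", {})[met["sample"]] = e["vid"] in chosen

    sample_meta = {r["sample"]: r for r in sample_rows}

    def draw_depth(mean: float) -> int:
        return max(int(rng.poisson(mean)), config.depth_floor)

    # per (variant, sample) planting
    for e in plan:
        if "vid" not in e:
            continue
        pat = next(p for p in patients if p["patient"] == e["patient"])
        patient_samples = [s["sample"] for s in pat["samples"]]
        per_sample: dict[str, dict] = {}
        for s_i, smp_name in enumerate(patient_samples):
            meta = sample_meta[smp_name]
            present = smp_name in e["present_samples"] or e["art"] == "germline_leak"
            cn, major = locus_cn(smp_name, e["chrom"], e["pos"])
            n_n = 1 if (e["chrom"] == config.sex_chrom and meta["sex"] == "male") else 2
            rho = meta["purity"]
            rec = dict(present=present, n_t=cn, major=major, n_n=n_n)
            if not present:
                rec.update(t_vaf=0.0, n_vaf=0.0, ccf=float("nan"), mult=0, timing="na")
            elif e["art"] == "germline_leak":
                t_vaf = float(rng.uniform(0.4, 0.55))
                n_vaf = float(rng.uniform(0.3, 0.5))
                rec.update(t_vaf=t_vaf, n_vaf=n_vaf, ccf=float("nan"), mult=0, timing="na")
            else:
                if smp_name == patient_samples[0]:
                    subclonal = e["primary_subclonal"]
                elif e["scope"] == "shared":
                    if e["primary_subclonal"]:
                        subclonal = not e.get("met_clonal", {}).get(smp_name, False)
                    else:
                        subclonal = False
                else:
                    subclonal = rng.random() < config.subclonal_fraction_primary
                ccf_val = (float(rng.uniform(*config.subclonal_ccf_range))
                           if subclonal else 1.0)
                if (not subclonal) and major >= 2 and rng.random() < config.clonal_early_rate:
                    mult = 2
                else:
                    mult = 1
                t_vaf = min(vaf_from_ccf(ccf_val, mult, rho, cn, n_n), 0.999)
                timing = ("subclonal" if subclonal
                          else ("clonal_early" if (major >= 2 and mult >= 2)
                                else ("clonal_late" if major >= 2 else "clonal_na")))
                rec.update(t_vaf=t_vaf, n_vaf=0.0, ccf=ccf_val, mult=mult, timing=timing)
            # integer counts
            t_depth = draw_depth(config.depth_mean_tumor)
            n_depth = draw_depth(config.depth_mean_normal)
            t_alt = int(round(rec["t_vaf"] * t_depth))
            if rec["present"] and t_alt == 0:
                t_alt = 1  # a planted variant always leaves at least one read
            n_alt = int(round(rec["n_vaf"] * n_depth))
            rec.update(t_alt=t_alt, t_ref=t_depth - t_alt,
                       n_alt=n_alt, n_ref=n_depth - n_alt)
            # caller membership
            if rec["present"]:
                called = tuple(c for c in e["eligible"] if rng.random() < sens.get(c, 0.0))
            else:
                called = ()
            rec["called"] = called
            per_sample[smp_name] = rec

            # pileup rows for every sample of the patient (tumor + normal)
            for tissue, alt_c, ref_c in (("tumor", rec["t_alt"], rec["t_ref"]),
                                         ("normal", rec["n_alt"], rec["n_ref"])):
                depth = alt_c + ref_c
                pileup_rows.append(dict(sample=smp_name, tissue=tissue,
                                        chrom=e["chrom"], pos=e["pos"],
                                        allele=e["ref"], count=ref_c, depth=depth))
                pileup_rows.append(dict(sample=smp_name, tissue=tissue,
                                        chrom=e["chrom"], pos=e["pos"],
                                        allele=e["alt"], count=alt_c, depth=depth))

        # validation-set membership (drawn once per variant)
        single_caller_samples = [s for s, r in per_sample.items() if len(r["called"]) == 1]
        in_lval = bool(single_caller_samples) and e["class_key"] != "DELINS" \
            and rng.random() < sens.get("lancet", 0.0)
        in_msv = e["class_key"] in ("INDEL_SHORT", "INDEL_LONG", "DELINS") \
            and rng.random() < sens.get("manta", 0.0)
        if in_lval:
            for s in single_caller_samples:
                lval_rows.append(dict(sample=s, chrom=e["chrom"], pos=e["pos"],
                                      ref=e["ref"], alt=e["alt"]))
        if in_msv:
            for s in patient_samples:
                msv_rows.append(dict(sample=s, chrom=e["chrom"], pos=e["pos"],
                                     ref=e["ref"], alt=e["alt"]))

        # emitted caller records
        for smp_name, rec in per_sample.items():
            for caller in rec["called"]:
                if e["class_key"] == "MNV" and caller == "strelka2":
                    for i, (r_b, a_b) in enumerate(zip(e["ref"], e["alt"])):
                        if r_b == a_b:
                            continue
                        call_rows.append(dict(
                            sample=smp_name, caller=caller, chrom=e["chrom"],
                            pos=e["pos"] + i, vid=e["vid"], ref=r_b, alt=a_b,
                            t_alt=rec["t_alt"], t_ref=rec["t_ref"],
                            n_alt=rec["n_alt"], n_ref=rec["n_ref"]))
                else:
                    row = dict(sample=smp_name, caller=caller, chrom=e["chrom"],
                               pos=e["pos"], vid=e["vid"], ref=e["ref"], alt=e["alt"],
                               t_alt=rec["t_alt"], t_ref=rec["t_ref"],
                               n_alt=rec["n_alt"], n_ref=rec["n_ref"])
                    if caller == "svaba":  # no reference counts reported
                        row["t_ref"] = row["n_ref"] = None
                    call_rows.append(row)

        # expected survival flags
        _expect_small(e, per_sample, in_lval, in_msv, config, truth_rows)

    # ---- structural variants -------------------------------------------
    sv_rows, sv_truth_rows, pon_sv_rows, germ_sv_rows, support_rows = \
        _plant_svs(config, patients, sample_meta, boundaries_by_patient,
                   seg_lookup, rng)

    # decoy database entries away from any planted event
    for chrom, length in config.genome[:1]:
        base = length - 40_000
        pon_sv_rows.append(dict(chrom1=chrom, pos1=base, strand1="+",
                                chrom2=chrom, pos2=base + 5_000, strand2="-",
                                n_individuals=1))
        germ_sv_rows.append(dict(chrom1=chrom, pos1=base + 12_000, strand1=".",
                                 chrom2=chrom, pos2=base + 20_000, strand2="."))

    def frame(rows, columns) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=columns)
        return df.sort_values(columns[: min(4, len(columns))]).reset_index(drop=True)

    return Cohort(
        config=config,
        samples=pd.DataFrame(sample_rows),
        small_calls=frame(call_rows, ["sample", "caller", "chrom", "pos", "vid",
                                      "ref", "alt", "t_alt", "t_ref", "n_alt", "n_ref"]),
        pileups=frame(pileup_rows, ["sample", "tissue", "chrom", "pos", "allele",
                                    "count", "depth"]),
        pon_snv=frame(pon_rows, ["chrom", "pos", "ref", "alt", "n_individuals"]),
        population_af=frame(af_rows, ["chrom", "pos", "ref", "alt", "kg_af", "gnomad_af"]),
        lancet_validation=frame(lval_rows, ["sample", "chrom", "pos", "ref", "alt"]),
        manta_smallsv=frame(msv_rows, ["sample", "chrom", "pos", "ref", "alt"]),
        segments=frame(seg_rows, ["sample", "chrom", "start", "end", "cn",
                                  "major_cn", "minor_cn"]),
        sv_calls=frame(sv_rows, ["sample", "caller", "chrom1", "pos1", "strand1",
                                 "chrom2", "pos2", "strand2", "svid",
                                 "t_split", "n_split"]),
        pon_sv=frame(pon_sv_rows, ["chrom1", "pos1", "strand1", "chrom2", "pos2",
                                   "strand2", "n_individuals"]),
        germline_sv=frame(germ_sv_rows, ["chrom1", "pos1", "strand1", "chrom2",
                                         "pos2", "strand2"]),
        sv_support=frame(support_rows, ["sample", "chrom1", "pos1", "strand1",
                                        "chrom2", "pos2", "strand2", "support"]),
        truth_small=frame(truth_rows, TRUTH_SMALL_COLUMNS),
        truth_sv=frame(sv_truth_rows, TRUTH_SV_COLUMNS),
        truth_fga=pd.DataFrame(fga_rows, columns=["sample", "fga"]),
    )


TRUTH_SMALL_COLUMNS = [
    "patient", "sample", "vid", "chrom", "pos", "ref", "alt", "var_class",
    "artifact", "present", "tumor_vaf", "normal_vaf", "t_alt", "t_ref",
    "n_alt", "n_ref", "ccf", "multiplicity", "n_t", "n_n", "major_cn",
    "timing", "callers", "in_lancet_validation", "in_manta_smallsv",
    "pon_count", "pop_af_max", "expect_flags", "expect_retained",
    "expect_rescued", "expect_final",
]

TRUTH_SV_COLUMNS = [
    "patient", "sample", "svid", "chrom1", "pos1", "strand1", "chrom2", "pos2",
    "strand2", "artifact", "present", "span", "callers", "t_split", "n_split",
    "cp_near", "pon_count", "in_germline_db", "size_filtered",
    "expect_retained", "expect_rescued", "expect_final",
]


def _expect_small(e: dict, per_sample: dict, in_lval: bool, in_msv: bool,
                  config: CohortConfig, truth_rows: list) -> None:
    """Compute expected filter flags / retention / rescue per sample."""
    class_map = {"SNV": "SNV", "MNV": "MNV", "INDEL_SHORT": "INDEL",
                 "INDEL_LONG": "INDEL", "DELINS": "DELINS"}
    retained: dict[str, bool] = {}
    details: dict[str, dict] = {}
    for smp, rec in per_sample.items():
        called = set(rec["called"])
        flags: list[str] = []
        counts_absent = False
        if rec["present"]:
            if e["class_key"] == "MNV" and not (called & {"mutect2", "lancet"}):
                # constituents stay individual SNVs with single-caller support
                effective_support = 1 if called else 0
                counts_absent = True  # per-base pileup rows are not emitted
            else:
                effective_support = len(called)
            if e["class_key"] in ("INDEL_LONG", "DELINS") and called <= {"svaba"}:
                counts_absent = True
            if e["pon_count"] >= 2:
                flags.append("PON")
            if max(e["kg_af"], e["gnomad_af"]) >= 0.01:
                flags.append("POP_AF")
            if not counts_absent and called:
                t_depth = rec["t_alt"] + rec["t_ref"]
                n_depth = rec["n_alt"] + rec["n_ref"]
                t_vaf = rec["t_alt"] / t_depth if t_depth else 0.0
                n_vaf = rec["n_alt"] / n_depth if n_depth else 0.0
                if t_vaf < 1e-4:
                    flags.append("LOW_TUMOR_VAF")
                if n_vaf > 0.2:
                    flags.append("HIGH_NORMAL_VAF")
                if t_depth < 2:
                    flags.append("LOW_TUMOR_DEPTH")
                if n_depth < 2:
                    flags.append("LOW_NORMAL_DEPTH")
                if n_vaf > t_vaf:
                    flags.append("NORMAL_GT_TUMOR")
            validated = in_lval or in_msv
            mnv_unfused_strelka = (e["class_key"] == "MNV"
                                   and not (called & {"mutect2", "lancet"}))
            ok_support = effective_support >= 2 or (
                effective_support == 1 and validated and not mnv_unfused_strelka
            )
            retained[smp] = bool(called) and not flags and ok_support
        else:
            retained[smp] = False
        details[smp] = dict(flags=flags)
    for smp, rec in per_sample.items():
        others = [s for s in per_sample if s != smp]
        resc = (not retained[smp]
                and any(retained[o] for o in others)
                and rec["t_alt"] > 0)
        if not rec["present"] and rec["t_alt"] == 0:
            resc = False
        if not (rec["present"] or resc):
            continue
        truth_rows.append(dict(
            patient=e["patient"], sample=smp, vid=e["vid"], chrom=e["chrom"],
            pos=e["pos"], ref=e["ref"], alt=e["alt"],
            var_class=class_map[e["class_key"]], artifact=e["art"],
            present=rec["present"], tumor_vaf=rec["t_vaf"], normal_vaf=rec["n_vaf"],
            t_alt=rec["t_alt"], t_ref=rec["t_ref"], n_alt=rec["n_alt"],
            n_ref=rec["n_ref"], ccf=rec["ccf"], multiplicity=rec["mult"],
            n_t=rec["n_t"], n_n=rec["n_n"], major_cn=rec["major"],
            timing=rec["timing"], callers=",".join(rec["called"]),
            in_lancet_validation=in_lval, in_manta_smallsv=in_msv,
            pon_count=e["pon_count"], pop_af_max=max(e["kg_af"], e["gnomad_af"]),
            expect_flags=",".join(details[smp]["flags"]),
            expect_retained=retained[smp], expect_rescued=resc,
            expect_final=retained[smp] or resc,
        ))


def _plant_svs(config: CohortConfig, patients: list, sample_meta: dict,
               boundaries: dict, seg_lookup: dict, rng: np.random.Generator):
    """Plant per-patient SV events and compute their expected survival."""
    sv_rows, truth_rows, pon_rows, germ_rows, support_rows = [], [], [], [], []
    used: dict[str, list[int]] = {c: [] for c, _ in config.genome}
    genome = dict(config.genome)
    svid_counter = 0

    def place(chrom: str, lo: int, hi: int) -> int:
        for _ in range(200):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - u) >= 2_000 for u in used[chrom]):
                used[chrom].append(pos)
                return pos
        raise ValueError(f"cannot place SV breakend on {chrom} without collision")

    def changepoints(sample: str) -> list[tuple[str, int]]:
        cps = []
        segs = sorted(seg_lookup[sample])
        for (c1, s1, e1, cn1, *_), (c2, s2, e2, cn2, *_) in zip(segs, segs[1:]):
            if c1 == c2 and e1 == s2 and cn1 != cn2:
                cps.append((c1, s2 + 1))
        return cps

    for pat in patients:
        names = [s["sample"] for s in pat["samples"]]
        n_samples = len(names)
        n_shared = int(round(config.shared_fraction * config.n_true_sv)) if n_samples > 1 else 0
        n_private = config.n_true_sv - n_shared
        jobs = [("shared", None)] * n_shared + [
            ("private", s) for s in names for _ in range(n_private)
        ]
        for scope, owner in jobs:
            svid_counter += 1
            svid = f"sv{svid_counter:04d}"
            small = rng.random() < config.small_sv_rate
            near_cp = (not small) and rng.random() < 0.4
            if rng.random() < 0.7 or len(config.genome) < 2:  # deletion-like
                chrom = config.genome[int(rng.integers(len(config.genome)))][0]
                length = genome[chrom]
                # small spans stay below the 500 bp size cutoff even after
                # per-breakend caller jitter
                small_hi = max(101, 500 - 2 * config.sv_jitter_max - 1)
                span = (int(rng.integers(100, small_hi)) if small
                        else int(rng.integers(20_000, min(800_000, length // 4))))
                if near_cp:
                    bnds = boundaries[pat["patient"]][chrom][1:-1]
                    anchor = int(rng.choice(bnds))
                    pos1 = min(max(anchor + int(rng.integers(-800, 801)), 10_000),
                               length - span - 10_000)
                    if not all(abs(pos1 - u) >= 2_000 for u in used[chrom]):
                        pos1 = place(chrom, 10_000, length - span - 10_000)
                    else:
                        used[chrom].append(pos1)
                else:
                    pos1 = place(chrom, 10_000, length - span - 10_000)
                pos2 = pos1 + span
                used[chrom].append(pos2)
                b1 = (chrom, pos1, "+")
                b2 = (chrom, pos2, "-")
            else:  # translocation
                idx = rng.choice(len(config.genome), size=2, replace=False)
                c1 = config.genome[int(idx[0])][0]
                c2 = config.genome[int(idx[1])][0]
                p1 = place(c1, 10_000, genome[c1] - 10_000)
                p2 = place(c2, 10_000, genome[c2] - 10_000)
                s1 = "+" if rng.random() < 0.5 else "-"
                s2 = "+" if rng.random() < 0.5 else "-"
                b1, b2 = (c1, p1, s1), (c2, p2, s2)
                if (b2[0], b2[1]) < (b1[0], b1[1]):
                    b1, b2 = b2, b1
                span = None
            r = rng.random()
            if r < config.pon_contamination_rate:
                art = "pon"
            elif r < config.pon_contamination_rate + config.germline_leak_rate:
                art = "germline"
            else:
                art = "somatic"
            pon_count = 0
            if art == "pon":
                pon_count = int(rng.integers(2, 4))
                pon_rows.append(dict(chrom1=b1[0], pos1=b1[1], strand1=b1[2],
                                     chrom2=b2[0], pos2=b2[1], strand2=b2[2],
                                     n_individuals=pon_count))
            if art == "germline":
                germ_rows.append(dict(chrom1=b1[0], pos1=b1[1], strand1=".",
                                      chrom2=b2[0], pos2=b2[1], strand2="."))

            present_samples = names if scope == "shared" else [owner]
            per_sample = {}
            for smp in names:
                present = smp in present_samples
                if present:
                    called = tuple(c for c in SV_CALLER_NAMES
                                   if rng.random() < config.caller_sensitivity.get(c, 0.0))
                    t_split = (3 + int(rng.poisson(4)) if rng.random() < 0.75
                               else int(rng.integers(0, 3)))
                    support = 1 + int(rng.poisson(8))
                else:
                    called, t_split, support = (), 0, 0
                per_sample[smp] = dict(present=present, called=called,
                                       t_split=t_split, n_split=0, support=support)
                support_rows.append(dict(sample=smp, chrom1=b1[0], pos1=b1[1],
                                         strand1=b1[2], chrom2=b2[0], pos2=b2[1],
                                         strand2=b2[2], support=support))
                for caller in called:
                    j1 = int(rng.integers(-config.sv_jitter_max, config.sv_jitter_max + 1))
                    j2 = int(rng.integers(-config.sv_jitter_max, config.sv_jitter_max + 1))
                    sv_rows.append(dict(sample=smp, caller=caller,
                                        chrom1=b1[0], pos1=b1[1] + j1, strand1=b1[2],
                                        chrom2=b2[0], pos2=b2[1] + j2, strand2=b2[2],
                                        svid=svid,
                                        t_split=per_sample[smp]["t_split"],
                                        n_split=0))

            size_filtered = span is not None and span < 500
            retained = {}
            for smp in names:
                rec = per_sample[smp]
                called = set(rec["called"])
                if not rec["present"] or size_filtered or not called:
                    retained[smp] = False
                    continue
                if pon_count >= 2 or art == "germline":
                    retained[smp] = False
                    continue
                if len(called) >= 2:
                    retained[smp] = True
                    continue
                if called & {"manta", "lumpy"}:
                    cps = changepoints(smp)
                    cp_near = any(
                        c == bc and abs(p - bp) <= 1000
                        for (c, p) in cps for (bc, bp, _s) in (b1, b2)
                    )
                    retained[smp] = cp_near or (
                        rec["t_split"] >= 3 and rec["n_split"] == 0
                    )
                else:
                    retained[smp] = False
            for smp in names:
                rec = per_sample[smp]
                others = [s for s in names if s != smp]
                resc = (not retained[smp] and not size_filtered
                        and any(retained[o] for o in others)
                        and rec["support"] > 0)
                if not (rec["present"] or resc):
                    continue
                cps = changepoints(smp)
                cp_near = any(
                    c == bc and abs(p - bp) <= 1000
                    for (c, p) in cps for (bc, bp, _s) in (b1, b2)
                )
                truth_rows.append(dict(
                    patient=pat["patient"], sample=smp, svid=svid,
                    chrom1=b1[0], pos1=b1[1], strand1=b1[2],
                    chrom2=b2[0], pos2=b2[1], strand2=b2[2],
                    artifact=art, present=rec["present"],
                    span=span if span is not None else -1,
                    callers=",".join(rec["called"]),
                    t_split=rec["t_split"], n_split=rec["n_split"],
                    cp_near=cp_near, pon_count=pon_count,
                    in_germline_db=art == "germline", size_filtered=size_filtered,
                    expect_retained=retained[smp], expect_rescued=resc,
                    expect_final=retained[smp] or resc,
                ))
    return sv_rows, truth_rows, pon_rows, germ_rows, support_rows


def generate_sv_jitter(pair: BreakpointPair, max_jitter: int,
                       rng: np.random.Generator | None = None) -> BreakpointPair:
    """A caller-replicate of ``pair``: breakends shifted by <= ``max_jitter``
    bp each, orientations preserved."""
    if max_jitter < 0:
        raise ValueError("max_jitter must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    if max_jitter == 0:
        return pair
    j1 = int(rng.integers(-max_jitter, max_jitter + 1))
    j2 = int(rng.integers(-max_jitter, max_jitter + 1))
    return BreakpointPair(
        a=Breakend(pair.a.chrom, pair.a.pos + j1, pair.a.orient),
        b=Breakend(pair.b.chrom, pair.b.pos + j2, pair.b.orient),
        sample=pair.sample, caller=pair.caller,
        t_split=pair.t_split, n_split=pair.n_split,
    )
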