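"""End-to-end orchestration: simulate -> consensus -> SV -> copy state -> clonality.

Each stage reads the cohort directory layout produced by
:meth:`consevo.synthetic.Cohort.write`, writes plain-text TSV outputs, and is
individually re-runnable.  A manifest of SHA-256 content hashes makes
rerun determinism checkable; all stages are pure functions of their inputs
and the run config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clonality as clon
from . import copystate as cs
from . import io as cio
from . import smallvar as sm
from . import sv as svmod
from .config import DEFAULT_THRESHOLDS, SMALLVAR_CALLERS, SV_CALLERS, Thresholds

logger = logging.getLogger("consevo")


@dataclass
class RunConfig:
    cohort_dir: Path
    outdir: Path
    thresholds: Thresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = DEFAULT_THRESHOLDS
        overrides = raw.get("thresholds", {})
        if overrides:
            for key in overrides:
                if not hasattr(thr, key):
                    raise ValueError(f"unknown threshold override: {key}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
            }
            thr = thr.replace(**coerced)
        return cls(cohort_dir=Path(raw["cohort_dir"]), outdir=Path(raw["outdir"]),
                   thresholds=thr, seed=int(raw.get("seed", 0)))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_smallvar_stage(cfg: RunConfig) -> dict[str, list[sm.ConsensusVariant]]:
    """Per-sample consensus + filters, then per-patient rescue; writes TSVs."""
    cohort = cfg.cohort_dir
    samples = cio.load_samples(cohort / "samples.tsv")
    pileup = cio.load_pileup(cohort / "pileups.tsv")
    pon = cio.load_pon_snv(cohort / "pon_snv.tsv")
    af = cio.load_population_af(cohort / "population_af.tsv")
    lval = cio.load_key_set(cohort / "lancet_validation.tsv")
    msv = cio.load_key_set(cohort / "manta_smallsv.tsv")
    thr = cfg.thresholds

    per_sample: dict[str, list[sm.ConsensusVariant]] = {}
    for sample in samples["sample"]:
        per_caller: dict[str, list[sm.VariantCall]] = {}
        for caller in SMALLVAR_CALLERS:
            path = cohort / "calls" / f"{sample}.{caller}.vcf"
            if not path.exists():
                continue
            per_caller[caller] = sm.split_mnvs(cio.read_caller_vcf(path, sample, caller))
        if not per_caller:
            raise FileNotFoundError(
                f"consensus stage: no caller call sets found for sample {sample} "
                f"under {cohort / 'calls'}"
            )
        merged = sm.merge_small_variants(per_caller)
        sm.assign_allele_counts(merged, pileup, sample,
                                max_pileup_len=thr.pileup_indel_max_len,
                                caller_order=thr.caller_count_order)
        sm.filter_pon(merged, pon, threshold=thr.pon_min_individuals)
        sm.filter_population_af(merged, af, max_af=thr.max_population_af)
        sm.filter_vaf_depth(merged, min_tumor_vaf=thr.min_tumor_vaf,
                            max_normal_vaf=thr.max_normal_vaf,
                            min_depth=thr.min_depth)
        sm.apply_retention(merged, lval.get(sample, set()), msv.get(sample, set()))
        per_sample[sample] = merged

    out: dict[str, list[sm.ConsensusVariant]] = {}
    for patient, group in samples.groupby("patient"):
        names = sorted(group["sample"])
        rescued = sm.rescue_multisample({s: per_sample[s] for s in names}, pileup)
        out.update(rescued)

    stage_dir = cfg.outdir / "consensus"
    stage_dir.mkdir(parents=True, exist_ok=True)
    for sample in sorted(out):
        rows = []
        for v in out[sample]:
            rows.append(dict(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                var_class=v.var_class, callers=",".join(sorted(v.callers)),
                n_callers=len(v.callers), t_alt=v.t_alt, t_ref=v.t_ref,
                n_alt=v.n_alt, n_ref=v.n_ref,
                tumor_vaf=v.tumor_vaf, normal_vaf=v.normal_vaf,
                counts_source=v.counts_source or "",
                flags=",".join(sorted(v.flags)),
                retained=v.retained, rescued=v.rescued, final=v.final,
            ))
        pd.DataFrame(rows).to_csv(stage_dir / f"{sample}.consensus.tsv",
                                  sep="\t", index=False, float_format="%.10g")
    return out


def run_sv_stage(cfg: RunConfig) -> dict[str, list[svmod.ConsensusSV]]:
    cohort = cfg.cohort_dir
    samples = cio.load_samples(cohort / "samples.tsv")
    thr = cfg.thresholds
    pon_pairs = [(p, x[0]) for p, x in
                 cio.read_bedpe(cohort / "pon_sv.bedpe", n_extra_ints=1)]
    germline = [p for p, _ in cio.read_bedpe(cohort / "germline_sv.bedpe")]
    support = cio.load_sv_support(cohort / "sv_support.tsv")
    segments = cio.load_segments(cohort / "segments.tsv")

    per_sample: dict[str, list[svmod.ConsensusSV]] = {}
    for sample in samples["sample"]:
        per_caller: dict[str, list[svmod.BreakpointPair]] = {}
        for caller in SV_CALLERS:
            path = cohort / "sv_calls" / f"{sample}.{caller}.bedpe"
            if not path.exists():
                continue
            pairs = []
            for pair, extras in cio.read_bedpe(path, sample, caller, n_extra_ints=2):
                pairs.append(svmod.BreakpointPair(
                    a=pair.a, b=pair.b, sample=sample, caller=caller,
                    t_split=extras[0], n_split=extras[1]))
            per_caller[caller] = svmod.filter_size(pairs, min_span=thr.sv_min_span)
        consensus = svmod.merge_svs(per_caller, slop=thr.sv_slop,
                                    reciprocal=thr.sv_reciprocal)
        svmod.filter_sv_pon_germline(consensus, pon_pairs, germline,
                                     slop=thr.sv_slop, reciprocal=thr.sv_reciprocal,
                                     pon_min_individuals=thr.pon_min_individuals)
        cps = cs.changepoints_from_segments(segments[sample])
        svmod.apply_sv_retention(consensus, cps,
                                 changepoint_window=thr.sv_changepoint_window,
                                 min_split_reads=thr.sv_min_split_reads)
        per_sample[sample] = consensus

    out: dict[str, list[svmod.ConsensusSV]] = {}
    for patient, group in samples.groupby("patient"):
        names = sorted(group["sample"])
        out.update(svmod.rescue_svs({s: per_sample[s] for s in names}, support,
                                    slop=thr.sv_slop, reciprocal=thr.sv_reciprocal))

    stage_dir = cfg.outdir / "sv"
    stage_dir.mkdir(parents=True, exist_ok=True)
    for sample in sorted(out):
        rows = []
        for c in out[sample]:
            rows.append(dict(
                chrom1=c.a.chrom, pos1=c.a.pos, strand1=c.a.orient,
                chrom2=c.b.chrom, pos2=c.b.pos, strand2=c.b.orient,
                callers=",".join(sorted(c.callers)), n_callers=len(c.callers),
                t_split=c.t_split, n_split=c.n_split,
                flags=",".join(sorted(c.flags)),
                retained=c.retained, rescued=c.rescued, final=c.final,
            ))
        pd.DataFrame(rows).to_csv(stage_dir / f"{sample}.sv.tsv",
                                  sep="\t", index=False)
    return out


def run_cnv_stage(cfg: RunConfig) -> pd.DataFrame:
    cohort = cfg.cohort_dir
    samples = cio.load_samples(cohort / "samples.tsv")
    segments = cio.load_segments(cohort / "segments.tsv")
    thr = cfg.thresholds
    genome = yaml.safe_load((cohort / "config.yaml").read_text())
    sex_chrom = genome.get("sex_chrom", "chrX")
    autosomes = [c for c, _ in genome["genome"] if c != sex_chrom]

    fga_rows, event_rows = [], []
    for row in samples.itertuples(index=False):
        neutral = cs.neutral_state(row.ploidy, thr.ploidy_frac_window)
        value = cs.fga(segments[row.sample], neutral, autosomes)
        fga_rows.append(dict(sample=row.sample, patient=row.patient,
                             ploidy=row.ploidy,
                             neutral=",".join(str(c) for c in sorted(neutral)),
                             fga=value))
        events = cs.annotate_fixed_loci(
            cs.classify_segments(segments[row.sample], row.ploidy,
                                 thr.ploidy_frac_window))
        for ev in events:
            event_rows.append(dict(
                sample=row.sample, chrom=ev.segment.chrom,
                start=ev.segment.start, end=ev.segment.end, cn=ev.segment.cn,
                state=ev.state, focal=ev.length <= thr.focal_max_len,
                labels=";".join(ev.labels),
            ))
    stage_dir = cfg.outdir / "cnv"
    stage_dir.mkdir(parents=True, exist_ok=True)
    fga_df = pd.DataFrame(fga_rows)
    fga_df.to_csv(stage_dir / "fga.tsv", sep="\t", index=False, float_format="%.12g")
    pd.DataFrame(event_rows).to_csv(stage_dir / "events.tsv", sep="\t", index=False)
    return fga_df


def run_clonality_stage(
    cfg: RunConfig,
    consensus: dict[str, list[sm.ConsensusVariant]],
) -> tuple[dict[str, dict], list[clon.TransitionSummary]]:
    """Time every final variant per sample; summarize per-pair transitions."""
    cohort = cfg.cohort_dir
    samples = cio.load_samples(cohort / "samples.tsv")
    segments = cio.load_segments(cohort / "segments.tsv")
    thr = cfg.thresholds
    genome = yaml.safe_load((cohort / "config.yaml").read_text())
    sex_chrom = genome.get("sex_chrom", "chrX")
    meta = {r.sample: r for r in samples.itertuples(index=False)}

    timing: dict[str, dict] = {}
    timing_rows = []
    for sample in sorted(consensus):
        m = meta[sample]
        segs = segments[sample]
        timing[sample] = {}
        for v in consensus[sample]:
            if not v.final:
                continue
            if v.t_alt is None or v.t_ref is None or (v.t_alt + v.t_ref) == 0:
                logger.warning("timing: no usable counts for %s:%s in %s",
                               v.chrom, v.pos, sample)
                continue
            seg = next((s for s in segs
                        if s.chrom == v.chrom and s.start < v.pos <= s.end), None)
            if seg is None:
                logger.warning("timing: no CN segment at %s:%s in %s",
                               v.chrom, v.pos, sample)
                continue
            n_n = 1 if (v.chrom == sex_chrom and m.sex == "male") else 2
            tm = clon.assign_timing(
                v.key, v.t_alt, v.t_ref, m.purity, seg.cn, n_n,
                major_cn=seg.major_cn,
                clonal_threshold=thr.clonal_ci_threshold,
                ci_level=thr.ccf_ci_level,
            )
            timing[sample][v.key] = tm
            timing_rows.append(dict(
                sample=sample, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                vaf=tm.f, multiplicity=tm.n, n_t=tm.n_t, n_n=tm.n_n,
                ccf=tm.ccf, ccf_lo=tm.ccf_lo, ccf_hi=tm.ccf_hi, timing=tm.timing,
                rescued=v.rescued,
            ))

    transitions: list[clon.TransitionSummary] = []
    for patient, group in samples.groupby("patient"):
        names = sorted(group["sample"])
        primary = names[0]
        for other in names[1:]:
            if primary not in timing or other not in timing:
                continue
            summary = clon.transition_summary(
                patient, primary, other,
                {k: t.timing for k, t in timing[primary].items()},
                {k: t.timing for k, t in timing[other].items()},
            )
            transitions.append(summary)

    stage_dir = cfg.outdir / "clonality"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(timing_rows).to_csv(stage_dir / "timing.tsv", sep="\t",
                                     index=False, float_format="%.10g")
    tr_rows = [dict(patient=t.patient, sample_from=t.sample_from,
                    sample_to=t.sample_to, n_shared=t.n_shared,
                    subclonal_to_clonal_fraction=(
                        t.subclonal_to_clonal_fraction
                        if t.subclonal_to_clonal_fraction is not None else "NA"))
               for t in transitions]
    pd.DataFrame(tr_rows, columns=["patient", "sample_from", "sample_to",
                                   "n_shared", "subclonal_to_clonal_fraction"]
                 ).to_csv(stage_dir / "transitions.tsv", sep="\t", index=False,
                          float_format="%.10g")

    # cohort-level sharing tally (within-patient dedup first)
    patient_sets: dict[str, list[set]] = {}
    groups = {}
    for row in samples.itertuples(index=False):
        keys = {v.key for v in consensus.get(row.sample, []) if v.final}
        patient_sets.setdefault(row.patient, []).append(keys)
        groups[row.patient] = ("prostate" if row.site_class == "prostate"
                               else "metastatic")
    tally = clon.cohort_sharing(patient_sets, groups)
    share_rows = [dict(chrom=k[0], pos=k[1], ref=k[2], alt=k[3],
                       n_patients=entry["n_patients"])
                  for k, entry in sorted(tally.items())]
    pd.DataFrame(share_rows, columns=["chrom", "pos", "ref", "alt", "n_patients"]
                 ).to_csv(stage_dir / "sharing.tsv", sep="\t", index=False)
    return timing, transitions


def summarize_cohort(cfg: RunConfig) -> pd.DataFrame:
    """Per-sample report assembled from the stage TSVs."""
    samples = cio.load_samples(cfg.cohort_dir / "samples.tsv")
    fga = pd.read_csv(cfg.outdir / "cnv" / "fga.tsv", sep="\t")
    timing = pd.read_csv(cfg.outdir / "clonality" / "timing.tsv", sep="\t")
    rows = []
    for row in samples.itertuples(index=False):
        cons = pd.read_csv(cfg.outdir / "consensus" / f"{row.sample}.consensus.tsv",
                           sep="\t")
        sv = pd.read_csv(cfg.outdir / "sv" / f"{row.sample}.sv.tsv", sep="\t")
        t = timing[timing["sample"] == row.sample]
        n_timed = len(t)
        clonal = int((t["timing"] != "subclonal").sum())
        rows.append(dict(
            sample=row.sample, patient=row.patient, site_class=row.site_class,
            purity=row.purity, ploidy=row.ploidy,
            fga=float(fga.loc[fga["sample"] == row.sample, "fga"].iloc[0]),
            n_final_smallvar=int(cons["final"].sum()) if len(cons) else 0,
            n_rescued_smallvar=int(cons["rescued"].sum()) if len(cons) else 0,
            n_final_sv=int(sv["final"].sum()) if len(sv) else 0,
            clonal_fraction=(clonal / n_timed) if n_timed else float("nan"),
        ))
    report = pd.DataFrame(rows)
    report.to_csv(cfg.outdir / "report.tsv", sep="\t", index=False,
                  float_format="%.10g")
    return report


def _manifest(outdir: Path) -> dict[str, str]:
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        # the config echo holds run-specific paths; it is provenance, not output
        if path.is_file() and path.name not in ("manifest.json", "run_config.yaml"):
            rel = path.relative_to(outdir).as_posix()
            hashes[rel] = hashlib.sha256(path.read_bytes()).hexdigest()
    return hashes


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Run every stage and write a manifest of output content hashes."""
    if not cfg.cohort_dir.exists():
        raise FileNotFoundError(f"cohort directory not found: {cfg.cohort_dir}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    # provenance echo of the effective config
    echo = dict(cohort_dir=str(cfg.cohort_dir), outdir=str(cfg.outdir),
                seed=cfg.seed,
                thresholds={k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in vars(cfg.thresholds).items()})
    (cfg.outdir / "run_config.yaml").write_text(
        yaml.safe_dump(echo, sort_keys=True))
    consensus = run_smallvar_stage(cfg)
    run_sv_stage(cfg)
    run_cnv_stage(cfg)
    run_clonality_stage(cfg, consensus)
    summarize_cohort(cfg)
    manifest = _manifest(cfg.outdir)
    (cfg.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
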