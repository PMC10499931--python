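# consevo

Multi-caller somatic consensus, copy-state and clonal-evolution analysis for
multi-sample tumor/normal whole-genome cohorts — with a synthetic cohort
generator that plants ground truth for every stage.

## What it does

Tumor WGS studies that profile several samples per patient (e.g. a primary
prostate tumor plus one or more metastases) typically run an ensemble of
variant callers and then apply a post-calling procedure to produce a final,
filtered, cross-sample-consistent call set. `consevo` implements that
procedure as a reusable, tested library:

1. **Small-variant consensus** — MNVs from phasing-aware callers are split
   into SNVs, calls are merged across callers on normalized
   `(chrom, pos, ref, alt)` keys, and MNVs are re-fused when every
   constituent SNV has identical caller support. Final allele counts come
   from a pileup (SNVs, indels < 10 nt) or from a fixed caller-preference
   order (Strelka2, MuTect2, Lancet) for longer events. Variants are
   filtered against a panel of normals (PON, ≥ 2 individuals), population
   allele frequency (MAF ≥ 1% in 1000 Genomes or gnomAD), tumor VAF
   < 10⁻⁴, normal VAF > 0.2, depth < 2, and normal VAF > tumor VAF;
   retained calls need ≥ 2 callers or one caller plus orthogonal validation.
   Across a patient's samples, retained variants missing from one sample
   are **rescued** there when the pileup shows VAF > 0.
2. **SV consensus** — breakpoint pairs match when corresponding breakends
   agree in orientation within 300 bp slop and (intra-chromosomal) spans
   overlap reciprocally ≥ 50%; events < 500 bp are excluded. Clusters are
   filtered against an SV PON and germline SV databases, and retained on
   multi-caller support or, for Manta/Lumpy singletons, a copy-number
   changepoint within 1 kb of a breakend or ≥ 3 tumor-only split reads.
   Multi-sample rescue uses per-sample read support.
3. **Copy state** — the copy-neutral state is defined by ploidy (a ploidy
   with fractional part in [0.4, 0.6], e.g. 3.5, has two neutral states
   {3, 4}); segments classify as loss (CN 0), deletion, neutral, gain, or
   amplification (CN > 2·ploidy). Fraction of genome altered (FGA) is the
   proportion of covered autosomal bases outside the neutral state. Focal
   events (≤ 3 Mb) are annotated against named loci; the AR enhancer
   (GRCh38 chrX:66,880,158–66,935,158) ships as the default.
4. **Clonality** — per mutation, the cancer cell fraction is

   CCF = f / (n·ρ) · (ρ·N_T + N_N·(1 − ρ))

   with VAF *f*, multiplicity *n*, purity ρ and tumor/normal local copy
   numbers N_T, N_N. A Wilson 95% CI on *f* is propagated through the
   formula; a mutation is clonal when the CCF CI upper bound ≥ 0.9, and
   clonal mutations in copy-gained regions split into clonal-early
   (n ≥ 2) vs clonal-late. Shared variants between a patient's samples are
   cross-tabulated by timing class, yielding the headline
   subclonal-to-clonal transition fraction, and cohort-wide sharing is
   tallied per patient.

Because the real cohorts such analyses run on are controlled-access, the
package includes a first-class **synthetic cohort generator**
(`consevo.synthetic`) that emulates the full input bundle — per-caller VCFs
and BEDPEs with controlled sensitivity and positional jitter, pileup tables,
PON and population-AF resources, copy segments, purity/ploidy/sex metadata —
with a truth table recording each planted record's expected fate at every
filter stage.

## Worked example

```bash
consevo simulate --outdir demo/cohort --seed 3 --patients 2
consevo all --cohort demo/cohort --outdir demo/out
head -4 demo/out/report.tsv
```

prints (abridged):

```
sample  patient site_class purity       ploidy fga          n_final_smallvar n_rescued_smallvar n_final_sv clonal_fraction
P01_S1  P01     prostate   0.8705097861 2      0.6711111111 43               1                  6          0.6976744186
P01_S2  P01     brain      0.7828648144 2      0.3961111111 41               1                  7          0.8048780488
P01_S3  P01     nonbrain   0.7232507761 2      0.6655555556 40               0                  7          0.825
```

Per sample: the purity/ploidy metadata, the fraction of the genome outside
the ploidy-defined neutral copy state (`fga`), the sizes of the final
(retained + rescued) small-variant and SV call sets, and the fraction of
timed mutations classified clonal. Stage-level outputs (per-variant
consensus TSVs, SV consensus, per-segment copy-state events, per-mutation
timing, per-pair transition fractions, cohort sharing) land under
`demo/out/`, together with a `manifest.json` of content hashes — rerunning
with the same seed reproduces every file byte for byte.

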