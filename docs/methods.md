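# Methods

This note documents the models, rules and numerical choices behind
`consevo`, and what the synthetic cohorts it ships with do and do not show
about real data.

## Small-variant consensus

Calls from a caller ensemble (MuTect2, Strelka2, Lancet for SNV/MNV/indel;
SvABA additionally for indels) are merged per sample on normalized variant
keys. Normalization trims shared suffix then prefix bases and adjusts the
position; full reference-guided left-alignment is not performed because the
supported padded representations (VCF-style anchored indels) reduce to the
same key under trimming. An MNV is split into its constituent SNVs at
positions where ref and alt differ (a fully normalized MNV differs at every
position); constituents remember their parent identity and are re-fused iff
every constituent carries an identical caller-support set. Deletion–
insertion (delins) events are kept as standalone records and never fused
with adjacent SNVs/indels.

Final allele counts: SNVs, MNVs and indels shorter than 10 nt use unique
read-pair pileup counts (the pileup input is assumed pre-filtered at
mapping and base quality ≥ 10 — the package consumes pileup tables, it does
not pile up reads). Longer indels and delins take the first complete
(tumor+normal, alt+ref) count set in the order Strelka2 → MuTect2 → Lancet;
a caller reporting alt but not ref counts is skipped. Events observed only
by a caller that reports no reference counts keep counts absent: they are
exempt from the VAF/depth filters (which cannot be evaluated) but remain
subject to PON, population-AF and retention rules.

Filters set independent flags: PON recurrence ≥ 2 individuals (the
threshold is read as ≥ 2, the stricter of the two plausible readings of
"two or more"), population MAF ≥ 0.01 in any source, tumor VAF < 10⁻⁴,
normal VAF > 0.2, tumor or normal depth < 2, and normal VAF > tumor VAF.
Retention requires an unflagged variant with ≥ 2 supporting callers, or one
caller plus membership in a supplied validation set (regional Lancet
validation calls, or indels corroborated by Manta's small-SV output; both
are inputs, not re-computed, since running the callers is out of scope).

Multi-sample rescue takes the union of retained variants across a
patient's samples; for each sample missing a union variant from its
retained set, the tumor VAF is recomputed from that sample's pileup and the
variant is rescued iff VAF > 0. Rescue deliberately applies to variants
filtered in one sample but retained in another — the cross-sample evidence
overrides the single-sample filter, mirroring how multi-region studies
recover shared truncal variants. Rescue uses the same pileup (hence the
same MQ/BQ ≥ 10 convention) as count assignment.

## SV consensus

Breakpoint pairs are canonically ordered (A ≤ B by chromosome, then
position). Two pairs match when corresponding breakends share a chromosome
and orientation and lie within 300 bp slop, and — intra-chromosomally —
spans overlap reciprocally by ≥ 50%. Reciprocal overlap is undefined across
chromosomes, so translocations match on orientation + slop alone; an
intra-chromosomal pair never matches an inter-chromosomal one. Orientation
"." (unoriented database entries) acts as a wildcard. Events with span
strictly below 500 bp are excluded before merging; translocations have no
span and always pass.

Merging is single-linkage clustering under the match predicate (pairwise
tools behave transitively only through chains; single linkage makes that
explicit and order-independent). The cluster representative takes the
per-breakend median position, lower-middle on even counts; cluster split
counts take the per-member maximum (normal split reads conservatively so —
any member's normal evidence blocks the "tumor-only" rule). Consensus
events matching a PON event seen in ≥ 2 individuals, or any germline-SV
database entry, are flagged and never retained. Retention otherwise needs
≥ 2 callers, or a Manta/Lumpy singleton with a copy-number changepoint
within 1000 bp of either breakend (changepoints are boundaries between
adjacent segments of differing integer copy number) or ≥ 3 split reads in
the tumor with none in the normal. Cross-sample rescue matches the retained
union against per-sample read-support tables and rescues on support > 0.

## Copy state

The neutral state of a sample is derived from its average ploidy: a
fractional part within [0.4, 0.6] (inclusive; the fractional part is
rounded to 9 decimals so that a stored 2.3999…96 still counts as 2.4)
yields both flanking integers, otherwise the rounded ploidy. Classification
relative to the neutral set: CN 0 is a loss (taking precedence over
deletion), CN below the neutral minimum a deletion, CN above the neutral
maximum a gain, and strictly above 2·ploidy an amplification — CN exactly
2·ploidy stays a gain. These five classes partition ℕ for every ploidy > 0
(property-tested). FGA is the altered fraction of covered autosomal bases;
uncovered bases are excluded from the denominator and sex chromosomes are
excluded entirely, though they still classify per segment. Focal events are
those ≤ 3 Mb. Named-locus annotation ships the AR enhancer (GRCh38
chrX:66,880,158–66,935,158) by default; a gain or amplification overlapping
a locus gets an additional "<locus> gain" label.

## Clonality

CCF = f/(n·ρ) · (ρ·N_T + N_N·(1 − ρ)). N_N comes from the sample's sex
metadata: 2 on autosomes, 1 on the sex chromosome of male patients.
Multiplicity is estimated as round(f/ρ · (ρ·N_T + N_N·(1 − ρ))) clamped to
[1, major CN] — for a clonal mutation this quantity equals n exactly, so
rounding is stable away from half-integer CCF·n.

Timing is a deterministic proxy for likelihood-based mutation timers, whose
full Bayesian machinery (bootstrap CIs, mixture posteriors) is out of
scope: a Wilson 95% CI on alt/(alt+ref) is propagated linearly through the
CCF formula (CCF is linear in f, so the interval maps exactly), and a
mutation is clonal iff the CCF CI upper bound ≥ 0.9. The threshold is
configurable (`Thresholds.clonal_ci_threshold`); it is a calibration of
this proxy, not of the original likelihood models, and classifications near
CCF ≈ 0.6 at low purity or high local CN are the least certain. Clonal
mutations on a gained major allele (major CN ≥ 2) split into clonal-early
(n ≥ 2: the mutation preceded the gain) and clonal-late (n = 1); clonal
mutations elsewhere are timing-uninformative (clonal_na). The headline
transition fraction pools the three clonal classes; with no shared
subclonal variants in the source sample it is undefined and reported NA.
Cohort sharing deduplicates within patient before counting patients per
variant identity, optionally stratified by group and restricted to a
region mask (e.g. noncoding intervals).

## Synthetic cohorts

`CohortConfig` defaults encode the emulated study conditions: 4 patients
with 1–3 samples each (primary prostate plus brain/non-brain metastases), a
three-chromosome toy genome (5 + 4 + 3 Mb with chrX as the sex chromosome),
~54 small variants and 8 SVs per sample, tumor depth Poisson around 90×
(floored at 20) and normal around 45× — near typical tumor ≈ 96×,
normal ≈ 48× WGS — purity uniform in (0.55, 0.95), ploidies {2.0, 2.2,
3.5} (including a half-integer exercising the two-state neutral window),
caller sensitivities 0.70–0.85 chosen so single-caller dropouts, validation
rescue and cross-sample rescue are all exercised, 5% PON contamination, 5%
germline leakage (normal VAF 0.3–0.5), 3% common-population variants, 60%
of a patient's variants shared across samples, 40% of the primary's
variants subclonal, and a primary→metastasis subclonal-to-clonal transition
fraction of 0.83. Transition planting rounds to the nearest integer count
and fixes the remainder assignment by the seed. Planted tumor VAFs invert
the CCF formula exactly at each locus (subclonal CCF uniform in [0.2, 0.5],
clonal CCF 1.0, multiplicity 2 with probability 0.3 on gained major
alleles); integer read counts are round(VAF·depth) with at least one alt
read for planted variants, so the only recovery noise is rounding and the
Poisson depth draw. Loci are allocated on a ≥ ~20 bp spacing grid and a
config whose genome cannot host the requested counts without collision is
rejected. Small SV spans are kept below 500 − 2·jitter bp so no caller
replicate can jitter across the size cutoff; large spans start at 20 kb so
jitter (default ≤ 80 bp, which also keeps any two replicates within the
300 bp pairwise slop) cannot break reciprocal overlap; breakends of
distinct events are kept ≥ 2 kb apart so clusters never bridge events.

The truth tables store, per planted record and sample, the caller draw,
planted VAF/CCF/multiplicity/timing, database memberships and the expected
flag/retention/rescue outcome computed from the same rules the pipeline
implements; an independently coded brute-force oracle (tests/_oracle.py)
re-derives the same outcomes from the emitted files alone, which is what
the equivalence tests compare against.

What the generator does **not** emulate: read-level artifacts (no
FASTQ/BAM; pileups are the ground truth), mapping ambiguity, indel
representation divergence between callers (all callers emit the normalized
allele), caller-specific error profiles, subclonal copy number, kataegis or
clustered mutation processes, and cross-patient variant sharing (loci are
globally unique, so cohort-sharing counts are exercised by unit tests, not
by the generator). Passing tests therefore demonstrate correctness of the
consensus/filter/rescue/timing logic under controlled inputs, not
robustness to upstream calling noise.

## Problem sizes and runtime

The test suite uses 2–4-patient cohorts (≤ 500 small variants, ≤ 200 SVs),
20 seeds for oracle equivalence, and 100 seeded replicates at n = 200
shared subclonal variants per planted transition fraction; the acceptance
script uses the same sizes with 40 transition replicates. These sizes keep
the whole verification run in the order of a minute while leaving every
rule on a code path exercised by multiple records per cohort.

## Interface notes

Stages are plain functions over a cohort directory; the CLI (`consevo
simulate|consensus|sv|cnv|clonality|report|all`) is a thin wrapper. The
`--threads` flag is accepted for interface compatibility; the pipeline is
single-process and results are independent of it. Outputs are
deterministic byte-for-byte under a fixed seed and config; the manifest
hashes every stage output (the run-config echo, which contains
run-specific paths, is provenance and excluded).
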