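"""Cancer cell fraction, mutation timing and clonal-transition analysis.

For a mutation with tumor VAF ``f``, multiplicity ``n`` (mutated copies per
tumor cell), tumor purity ``rho``, tumor total copy number ``N_T`` and
normal total copy number ``N_N`` at the locus, the cancer cell fraction is

    CCF = f / (n * rho) * (rho * N_T + N_N * (1 - rho))

Timing is a deterministic proxy for likelihood-based mutation timers: a
Wilson 95% confidence interval on the VAF is propagated linearly through
the CCF formula, a mutation is clonal iff the CCF CI upper bound reaches a
threshold (default 0.9), and clonal mutations in copy-gained regions
(major allele CN >= 2) are split into clonal-early (multiplicity >= 2,
mutation preceding the gain) and clonal-late (multiplicity 1); clonal
mutations elsewhere are timing-uninformative (clonal_na).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger("consevo")

TIMING_CLONAL_EARLY = "clonal_early"
TIMING_CLONAL_LATE = "clonal_late"
TIMING_CLONAL_NA = "clonal_na"
TIMING_SUBCLONAL = "subclonal"
CLONAL_CLASSES = frozenset({TIMING_CLONAL_EARLY, TIMING_CLONAL_LATE, TIMING_CLONAL_NA})


def ccf(f: float, n: int, rho: float, n_t: float, n_n: float) -> float:
    """Cancer cell fraction from VAF, multiplicity, purity and copy number."""
    if n < 1:
        raise ValueError("multiplicity must be >= 1")
    if not (0 < rho <= 1):
        raise ValueError("purity must be in (0, 1]")
    if n_t < 0:
        raise ValueError("tumor copy number must be >= 0")
    return f / (n * rho) * (rho * n_t + n_n * (1 - rho))


def vaf_from_ccf(ccf_value: float, n: int, rho: float, n_t: float, n_n: float) -> float:
    """Inverse of :func:`ccf`: the tumor VAF implied by a planted CCF."""
    denom = rho * n_t + n_n * (1 - rho)
    if denom <= 0:
        raise ValueError("degenerate locus: rho*N_T + N_N*(1-rho) <= 0")
    return ccf_value * n * rho / denom


def estimate_multiplicity(f: float, rho: float, n_t: float, n_n: float,
                          major_cn: int | None = None) -> int:
    """Integer multiplicity estimate, clamped to [1, major CN].

    Rounds f/rho * (rho*N_T + N_N*(1-rho)) — the mutation copy number per
    tumor cell for a fully clonal mutation — and clamps to the available
    allele copies (major CN when known, else total CN, else 1).
    """
    if not (0 < rho <= 1):
        raise ValueError("purity must be in (0, 1]")
    raw = f / rho * (rho * n_t + n_n * (1 - rho))
    upper = major_cn if major_cn is not None else (int(n_t) if n_t >= 1 else 1)
    upper = max(int(upper), 1)
    return min(max(int(round(raw)), 1), upper)


def ccf_interval(alt: int, total: int, n: int, rho: float, n_t: float, n_n: float,
                 level: float = 0.95) -> tuple[float, float]:
    """Wilson CI on the VAF propagated linearly through the CCF formula."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    lo, hi = proportion_confint(alt, total, alpha=1 - level, method="wilson")
    return (ccf(float(lo), n, rho, n_t, n_n), ccf(float(hi), n, rho, n_t, n_n))


@dataclass(frozen=True)
class TimedMutation:
    """A consensus variant with its CCF, multiplicity and timing class."""

    key: tuple[str, int, str, str]
    f: float
    n: int
    n_t: float
    n_n: float
    ccf: float
    ccf_lo: float
    ccf_hi: float
    timing: str


def assign_timing(
    key: tuple[str, int, str, str],
    alt: int,
    ref: int,
    rho: float,
    n_t: float,
    n_n: float,
    major_cn: int | None = None,
    clonal_threshold: float = 0.9,
    ci_level: float = 0.95,
) -> TimedMutation:
    """Time one mutation from its final allele counts and copy-number context.

    Clonal iff the CCF CI upper bound >= ``clonal_threshold``; clonal
    mutations on a gained major allele (major CN >= 2) split into early
    (n >= 2) vs late (n == 1), others are clonal_na.
    """
    total = alt + ref
    f = alt / total if total else 0.0
    n = estimate_multiplicity(f, rho, n_t, n_n, major_cn)
    value = ccf(f, n, rho, n_t, n_n)
    lo, hi = ccf_interval(alt, total, n, rho, n_t, n_n, level=ci_level)
    if hi >= clonal_threshold:
        if major_cn is not None and major_cn >= 2:
            timing = TIMING_CLONAL_EARLY if n >= 2 else TIMING_CLONAL_LATE
        else:
            timing = TIMING_CLONAL_NA
    else:
        timing = TIMING_SUBCLONAL
    return TimedMutation(key=key, f=f, n=n, n_t=n_t, n_n=n_n,
                         ccf=value, ccf_lo=lo, ccf_hi=hi, timing=timing)


# ---------------------------------------------------------------------------
# shared variants and transitions
# ---------------------------------------------------------------------------

def match_shared(
    keys_a: Iterable[tuple], keys_b: Iterable[tuple]
) -> tuple[set, set, set]:
    """Partition two samples' variant keys into (shared, private_a, private_b)."""
    a, b = set(keys_a), set(keys_b)
    shared = a & b
    return shared, a - shared, b - shared


@dataclass(frozen=True)
class TransitionSummary:
    """Cross-tabulated timing classes of variants shared by a sample pair."""

    patient: str
    sample_from: str
    sample_to: str
    counts: tuple[tuple[tuple[str, str], int], ...]  # ((timing_from, timing_to), n)
    n_shared: int
    subclonal_to_clonal_fraction: float | None  # None when no shared subclonal

    def count(self, t_from: str, t_to: str) -> int:
        return dict(self.counts).get((t_from, t_to), 0)


def transition_summary(
    patient: str,
    sample_from: str,
    sample_to: str,
    timing_from: Mapping[tuple, str],
    timing_to: Mapping[tuple, str],
) -> TransitionSummary:
    """Summarize timing transitions over the shared variants of a sample pair.

    The headline fraction pools clonal_early/late/na as "clonal":
    #(subclonal in the from-sample -> clonal in the to-sample) over all
    shared variants subclonal in the from-sample.  With an empty
    denominator the fraction is undefined (None).
    """
    shared = set(timing_from) & set(timing_to)
    counts: dict[tuple[str, str], int] = {}
    sub_from = 0
    sub_to_clonal = 0
    for key in shared:
        tf, tt = timing_from[key], timing_to[key]
        counts[(tf, tt)] = counts.get((tf, tt), 0) + 1
        if tf == TIMING_SUBCLONAL:
            sub_from += 1
            if tt in CLONAL_CLASSES:
                sub_to_clonal += 1
    frac = sub_to_clonal / sub_from if sub_from else None
    return TransitionSummary(
        patient=patient,
        sample_from=sample_from,
        sample_to=sample_to,
        counts=tuple(sorted(counts.items())),
        n_shared=len(shared),
        subclonal_to_clonal_fraction=frac,
    )


def cohort_sharing(
    patient_sets: Mapping[str, Iterable[set]],
    groups: Mapping[str, str] | None = None,
    mask: Sequence[tuple[str, int, int]] | None = None,
) -> dict[tuple, dict]:
    """Count, per variant identity, the number of distinct patients carrying it.

    ``patient_sets`` maps patient -> iterable of per-sample variant-key
    sets; keys are deduplicated within a patient first, so a variant in
    several samples of one patient counts once.  ``groups`` optionally maps
    patient -> group label to stratify counts; ``mask`` optionally restricts
    to variants inside the given (chrom, start, end) 0-based half-open
    intervals (e.g. a noncoding mask).
    """
    def in_mask(key: tuple) -> bool:
        if mask is None:
            return True
        chrom, pos = key[0], key[1]
        return any(c == chrom and start < pos <= end for c, start, end in mask)

    tally: dict[tuple, dict] = {}
    for patient in sorted(patient_sets):
        patient_union: set = set()
        for s in patient_sets[patient]:
            patient_union |= set(s)
        for key in patient_union:
            if not in_mask(key):
                continue
            entry = tally.setdefault(key, {"patients": set(), "by_group": {}})
            entry["patients"].add(patient)
            if groups is not None:
                g = groups.get(patient, "unknown")
                entry["by_group"].setdefault(g, set()).add(patient)
    for entry in tally.values():
        entry["n_patients"] = len(entry["patients"])
    return tally
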