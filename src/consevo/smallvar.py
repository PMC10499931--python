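"""Multi-caller SNV/MNV/indel consensus, filtering and multi-sample rescue.

The stage order mirrors the post-calling procedure for tumor/normal WGS
ensemble calling:

1. split caller-reported MNVs into constituent SNVs,
2. merge calls across callers on normalized (chrom, pos, ref, alt) keys and
   re-fuse MNVs whose constituent SNVs share identical caller support,
3. choose final allele counts (pileup for SNVs and short indels; a fixed
   caller-preference order for long indels and deletion-insertion events),
4. flag variants against a panel of normals, population allele frequencies
   and VAF/depth rules,
5. retain multi-caller calls (or validated single-caller calls), and
6. rescue retained variants into a patient's other samples when the pileup
   shows non-zero allele frequency there.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("consevo")

# filter flag names
FLAG_PON = "PON"
FLAG_POP_AF = "POP_AF"
FLAG_LOW_TUMOR_VAF = "LOW_TUMOR_VAF"
FLAG_HIGH_NORMAL_VAF = "HIGH_NORMAL_VAF"
FLAG_LOW_TUMOR_DEPTH = "LOW_TUMOR_DEPTH"
FLAG_LOW_NORMAL_DEPTH = "LOW_NORMAL_DEPTH"
FLAG_NORMAL_GE_TUMOR = "NORMAL_GT_TUMOR"

ALL_FLAGS = (
    FLAG_PON,
    FLAG_POP_AF,
    FLAG_LOW_TUMOR_VAF,
    FLAG_HIGH_NORMAL_VAF,
    FLAG_LOW_TUMOR_DEPTH,
    FLAG_LOW_NORMAL_DEPTH,
    FLAG_NORMAL_GE_TUMOR,
)

CLASS_SNV = "SNV"
CLASS_MNV = "MNV"
CLASS_INDEL = "INDEL"
CLASS_DELINS = "DELINS"


# ---------------------------------------------------------------------------
# keys and normalization
# ---------------------------------------------------------------------------

VariantKey = tuple[str, int, str, str]


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class from the (already trimmed) allele pair."""
    if len(ref) == 1 and len(alt) == 1:
        return CLASS_SNV
    if len(ref) == len(alt):
        return CLASS_MNV
    if len(ref) > 1 and len(alt) > 1:
        return CLASS_DELINS
    return CLASS_INDEL


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Trim shared suffix then prefix bases, adjusting ``pos``.

    Callers differ in indel representation (padded vs minimal); merging and
    PON/population lookups use this normalized key.  Full left-alignment
    against a reference is not needed for the padded representations the
    supported callers emit.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim common suffix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # anchor-base trim for pure ins/del handled by the loops above
    return (chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One allele-level call from one caller in one sample."""

    sample: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str
    t_alt: int | None = None
    t_ref: int | None = None
    n_alt: int | None = None
    n_ref: int | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def var_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> VariantKey:
        return normalize_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusVariant:
    """A merged variant with caller support, chosen counts and filter state."""

    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    parent_mnv: str | None = None
    #: per-caller reported counts, caller -> (t_alt, t_ref, n_alt, n_ref)
    caller_counts: dict[str, tuple[int | None, int | None, int | None, int | None]] = field(
        default_factory=dict
    )
    t_alt: int | None = None
    t_ref: int | None = None
    n_alt: int | None = None
    n_ref: int | None = None
    counts_source: str | None = None  # "pileup" | caller name | None
    flags: set[str] = field(default_factory=set)
    retained: bool = False
    rescued: bool = False

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def var_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def tumor_vaf(self) -> float | None:
        if self.t_alt is None or self.t_ref is None or (self.t_alt + self.t_ref) == 0:
            return None
        return self.t_alt / (self.t_alt + self.t_ref)

    @property
    def normal_vaf(self) -> float | None:
        if self.n_alt is None or self.n_ref is None or (self.n_alt + self.n_ref) == 0:
            return None
        return self.n_alt / (self.n_alt + self.n_ref)

    @property
    def final(self) -> bool:
        return self.retained or self.rescued


def indel_length(ref: str, alt: str) -> int:
    """Length of an indel or delins event: net or replaced bases."""
    return max(len(ref), len(alt)) - 1 if len(ref) != len(alt) else len(ref)


# ---------------------------------------------------------------------------
# 1. MNV splitting
# ---------------------------------------------------------------------------

def split_mnvs(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Replace each MNV with its constituent SNVs tagged with a parent id.

    Callers that phase adjacent substitutions report MNVs; callers that do
    not report the constituent SNVs.  Splitting first puts every caller on
    SNV keys so support sets are comparable; :func:`merge_small_variants`
    re-fuses them when support is uniform.  Positions where ref and alt
    agree carry no variant and are skipped (a fully normalized MNV has
    none).  Malformed MNV-like records with length mismatch are rejected
    with a warning.
    """
    out: list[VariantCall] = []
    for call in calls:
        if call.var_class != CLASS_MNV:
            out.append(call)
            continue
        if len(call.ref) != len(call.alt):  # defensive; class check implies equal
            logger.warning("rejecting malformed MNV %s:%s %s>%s",
                           call.chrom, call.pos, call.ref, call.alt)
            continue
        parent = f"{call.chrom}:{call.pos}:{call.ref}>{call.alt}"
        for i, (r, a) in enumerate(zip(call.ref, call.alt)):
            if r == a:
                continue
            out.append(
                SplitSnv(
                    sample=call.sample,
                    chrom=call.chrom,
                    pos=call.pos + i,
                    ref=r,
                    alt=a,
                    caller=call.caller,
                    t_alt=call.t_alt,
                    t_ref=call.t_ref,
                    n_alt=call.n_alt,
                    n_ref=call.n_ref,
                    parent=parent,
                )
            )
    return out


@dataclass(frozen=True)
class SplitSnv(VariantCall):
    """SNV produced by splitting an MNV; remembers its parent identity."""

    parent: str | None = None


# ---------------------------------------------------------------------------
# 2. cross-caller merge and MNV re-fusion
# ---------------------------------------------------------------------------

def merge_small_variants(
    per_caller: Mapping[str, Sequence[VariantCall]],
) -> list[ConsensusVariant]:
    """Merge one sample's calls across callers into consensus records.

    Keys are normalized (chrom, pos, ref, alt).  SNVs that were split from a
    common parent MNV are fused back into that MNV iff every constituent SNV
    has an identical caller-support set; otherwise they are emitted as
    individual SNVs.  Deletion-insertion events are kept as their own
    records and never fused with adjacent SNVs/indels.
    """
    # key -> caller -> counts; and key -> set of parent MNV ids
    support: dict[VariantKey, dict[str, tuple]] = defaultdict(dict)
    parents: dict[VariantKey, set[str]] = defaultdict(set)
    for caller in sorted(per_caller):
        for call in per_caller[caller]:
            key = call.key
            counts = (call.t_alt, call.t_ref, call.n_alt, call.n_ref)
            if caller in support[key]:
                logger.debug("duplicate record from %s at %s; deduplicated", caller, key)
            support[key][caller] = counts
            if isinstance(call, SplitSnv) and call.parent is not None:
                parents[key].add(call.parent)

    fused_keys: set[VariantKey] = set()
    out: list[ConsensusVariant] = []

    # attempt MNV re-fusion, parent by parent
    all_parents = sorted({p for ps in parents.values() for p in ps})
    for parent in all_parents:
        chrom, pos_s, alleles = parent.split(":")
        pos = int(pos_s)
        ref, alt = alleles.split(">")
        keys = [
            (chrom, pos + i, r, a)
            for i, (r, a) in enumerate(zip(ref, alt))
            if r != a
        ]
        if not all(k in support for k in keys):
            continue
        supports = [frozenset(support[k]) for k in keys]
        if len(set(supports)) != 1:
            continue  # uneven support: leave as individual SNVs
        callers = supports[0]
        caller_counts = {c: support[keys[0]][c] for c in sorted(callers)}
        out.append(
            ConsensusVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                callers=callers, parent_mnv=parent, caller_counts=caller_counts,
            )
        )
        fused_keys.update(keys)

    for key in sorted(support):
        if key in fused_keys:
            continue
        chrom, pos, ref, alt = key
        callers = frozenset(support[key])
        out.append(
            ConsensusVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                callers=callers,
                parent_mnv=min(parents[key]) if parents.get(key) else None,
                caller_counts={c: support[key][c] for c in sorted(callers)},
            )
        )
    out.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return out


# ---------------------------------------------------------------------------
# 3. final allele counts
# ---------------------------------------------------------------------------

class Pileup:
    """Unique read-pair counts per (sample, tissue, locus, allele).

    Stands in for a BAM pileup; counts are assumed pre-filtered at mapping
    and base quality >= 10.  ``depth`` is the total depth at the locus.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str, str, int, str], tuple[int, int]] = {}

    def add(self, sample: str, tissue: str, chrom: str, pos: int, allele: str,
            count: int, depth: int) -> None:
        if count < 0 or count > depth:
            raise ValueError("pileup count must satisfy 0 <= count <= depth")
        self._data[(sample, tissue, chrom, pos, allele)] = (count, depth)

    def lookup(self, sample: str, tissue: str, chrom: str, pos: int,
               allele: str) -> tuple[int, int] | None:
        return self._data.get((sample, tissue, chrom, pos, allele))


def assign_allele_counts(
    variants: list[ConsensusVariant],
    pileup: Pileup,
    sample: str,
    max_pileup_len: int = 10,
    caller_order: Sequence[str] = ("strelka2", "mutect2", "lancet"),
) -> list[ConsensusVariant]:
    """Choose final tumor/normal allele counts per consensus variant.

    SNVs, MNVs and indels shorter than ``max_pileup_len`` take counts from
    the pileup.  Longer indels and delins events take the first complete
    count set in ``caller_order``.  Variants with no usable source (e.g. a
    long indel called only by a caller that reports no reference counts)
    keep counts absent; they are exempted from VAF/depth filters downstream
    but remain subject to PON/population/retention rules.
    """
    for v in variants:
        cls = v.var_class
        use_pileup = cls in (CLASS_SNV, CLASS_MNV) or (
            cls == CLASS_INDEL and indel_length(v.ref, v.alt) < max_pileup_len
        )
        if use_pileup:
            t_alt = pileup.lookup(sample, "tumor", v.chrom, v.pos, v.alt)
            t_ref = pileup.lookup(sample, "tumor", v.chrom, v.pos, v.ref)
            n_alt = pileup.lookup(sample, "normal", v.chrom, v.pos, v.alt)
            n_ref = pileup.lookup(sample, "normal", v.chrom, v.pos, v.ref)
            if t_alt is None or t_ref is None or n_alt is None or n_ref is None:
                logger.warning("pileup missing at %s:%d for %s>%s; counts absent",
                               v.chrom, v.pos, v.ref, v.alt)
                continue
            v.t_alt, v.t_ref = t_alt[0], t_ref[0]
            v.n_alt, v.n_ref = n_alt[0], n_ref[0]
            v.counts_source = "pileup"
        else:
            for caller in caller_order:
                counts = v.caller_counts.get(caller)
                if counts is None or any(c is None for c in counts):
                    continue  # caller absent or incomplete: fall through
                v.t_alt, v.t_ref, v.n_alt, v.n_ref = counts
                v.counts_source = caller
                break
    return variants


# ---------------------------------------------------------------------------
# 4. filters
# ---------------------------------------------------------------------------

def filter_pon(
    variants: list[ConsensusVariant],
    pon: Mapping[VariantKey, int],
    threshold: int = 2,
) -> list[ConsensusVariant]:
    """Flag variants seen in >= ``threshold`` individuals of the PON."""
    for v in variants:
        if pon.get(v.key, 0) >= threshold:
            v.flags.add(FLAG_PON)
    return variants


def filter_population_af(
    variants: list[ConsensusVariant],
    af_table: Mapping[VariantKey, Mapping[str, float]],
    max_af: float = 0.01,
) -> list[ConsensusVariant]:
    """Flag variants at population MAF >= ``max_af`` in any source."""
    for v in variants:
        afs = af_table.get(v.key)
        if afs and any(a >= max_af for a in afs.values()):
            v.flags.add(FLAG_POP_AF)
    return variants


def filter_vaf_depth(
    variants: list[ConsensusVariant],
    min_tumor_vaf: float = 1e-4,
    max_normal_vaf: float = 0.2,
    min_depth: int = 2,
) -> list[ConsensusVariant]:
    """Flag on tumor VAF, normal VAF, depth, and normal-vs-tumor VAF.

    Variants with absent counts cannot be evaluated and receive no flags
    here.
    """
    for v in variants:
        if v.t_alt is None or v.t_ref is None or v.n_alt is None or v.n_ref is None:
            continue
        t_depth = v.t_alt + v.t_ref
        n_depth = v.n_alt + v.n_ref
        t_vaf = v.t_alt / t_depth if t_depth else 0.0
        n_vaf = v.n_alt / n_depth if n_depth else 0.0
        if t_vaf < min_tumor_vaf:
            v.flags.add(FLAG_LOW_TUMOR_VAF)
        if n_vaf > max_normal_vaf:
            v.flags.add(FLAG_HIGH_NORMAL_VAF)
        if t_depth < min_depth:
            v.flags.add(FLAG_LOW_TUMOR_DEPTH)
        if n_depth < min_depth:
            v.flags.add(FLAG_LOW_NORMAL_DEPTH)
        if n_vaf > t_vaf:
            v.flags.add(FLAG_NORMAL_GE_TUMOR)
    return variants


# ---------------------------------------------------------------------------
# 5. retention
# ---------------------------------------------------------------------------

def apply_retention(
    variants: list[ConsensusVariant],
    lancet_validation: frozenset[VariantKey] | set[VariantKey] = frozenset(),
    manta_small_svs: frozenset[VariantKey] | set[VariantKey] = frozenset(),
) -> list[ConsensusVariant]:
    """Retain unflagged variants with multi-caller or validated support."""
    validated = set(lancet_validation) | set(manta_small_svs)
    for v in variants:
        multi = len(v.callers) >= 2
        single_validated = len(v.callers) == 1 and v.key in validated
        v.retained = not v.flags and (multi or single_validated)
    return variants


# ---------------------------------------------------------------------------
# 6. multi-sample rescue
# ---------------------------------------------------------------------------

def rescue_multisample(
    sample_variants: Mapping[str, list[ConsensusVariant]],
    pileup: Pileup,
) -> dict[str, list[ConsensusVariant]]:
    """Rescue patient-union variants into samples where they were not retained.

    For each variant retained in at least one of the patient's samples and
    absent from another sample's retained set, the tumor VAF in that sample
    is recomputed from the pileup; the variant is rescued there iff VAF > 0.
    With fewer than two samples this is a no-op.
    """
    samples = sorted(sample_variants)
    out = {s: list(sample_variants[s]) for s in samples}
    if len(samples) < 2:
        return out

    union: dict[VariantKey, ConsensusVariant] = {}
    for s in samples:
        for v in sample_variants[s]:
            if v.retained and v.key not in union:
                union[v.key] = v

    for s in samples:
        retained_keys = {v.key for v in sample_variants[s] if v.retained}
        existing = {v.key: v for v in out[s]}
        for key in sorted(union):
            if key in retained_keys:
                continue
            chrom, pos, ref, alt = key
            t_alt = pileup.lookup(s, "tumor", chrom, pos, alt)
            t_ref = pileup.lookup(s, "tumor", chrom, pos, ref)
            if t_alt is None or t_ref is None:
                logger.warning("rescue: pileup missing for %s at %s:%d; skipped",
                               s, chrom, pos)
                continue
            depth = t_alt[0] + t_ref[0]
            if depth == 0 or t_alt[0] == 0:
                continue
            n_alt = pileup.lookup(s, "normal", chrom, pos, alt)
            n_ref = pileup.lookup(s, "normal", chrom, pos, ref)
            if key in existing:
                v = existing[key]
                v.rescued = True
                if v.t_alt is None:
                    v.t_alt, v.t_ref = t_alt[0], t_ref[0]
                    v.counts_source = "pileup"
            else:
                out[s].append(
                    ConsensusVariant(
                        chrom=chrom, pos=pos, ref=ref, alt=alt,
                        callers=frozenset(),
                        t_alt=t_alt[0], t_ref=t_ref[0],
                        n_alt=n_alt[0] if n_alt else None,
                        n_ref=n_ref[0] if n_ref else None,
                        counts_source="pileup",
                        rescued=True,
                    )
                )
        out[s].sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return out
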