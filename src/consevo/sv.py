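"""Structural-variant consensus: breakpoint matching, merging and evidence rules.

Breakpoint pairs from multiple SV callers are matched with per-breakend slop,
identical strand orientation and (for intra-chromosomal events) reciprocal
span overlap, then clustered by single linkage.  Consensus events are
filtered against an SV panel of normals and germline SV databases, retained
on multi-caller support or on orthogonal evidence (nearby copy-number
changepoint or tumor-only split reads), and rescued across a patient's
samples on non-zero read support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import SV_EVIDENCE_CALLERS

logger = logging.getLogger("consevo")

FLAG_SV_PON = "PON"
FLAG_SV_GERMLINE = "GERMLINE_DB"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 1-based
    orient: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orient not in ("+", "-", "."):
            raise ValueError(f"invalid orientation {self.orient!r}")


@dataclass(frozen=True)
class BreakpointPair:
    """Two oriented breakends; canonical order (A <= B by chrom, then pos)."""

    a: Breakend
    b: Breakend
    sample: str = ""
    caller: str = ""
    t_split: int = 0
    n_split: int = 0

    def __post_init__(self) -> None:
        if (self.b.chrom, self.b.pos) < (self.a.chrom, self.a.pos):
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @property
    def intra(self) -> bool:
        return self.a.chrom == self.b.chrom

    @property
    def span(self) -> int | None:
        """posB - posA for intra-chromosomal pairs, else None."""
        return self.b.pos - self.a.pos if self.intra else None


def reciprocal_overlap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> float:
    """min(overlap/lenA, overlap/lenB); 0 when either length is 0."""
    len_a, len_b = a_hi - a_lo, b_hi - b_lo
    if len_a <= 0 or len_b <= 0:
        return 0.0
    overlap = min(a_hi, b_hi) - max(a_lo, b_lo)
    if overlap <= 0:
        return 0.0
    return min(overlap / len_a, overlap / len_b)


def match_pairs(
    p: BreakpointPair,
    q: BreakpointPair,
    slop: int = 300,
    reciprocal: float = 0.5,
    require_orientation: bool = True,
) -> bool:
    """True iff two breakpoint pairs describe the same event.

    Corresponding breakends must lie within ``slop`` bp of each other with
    matching orientation; intra-chromosomal pairs must additionally overlap
    reciprocally by >= ``reciprocal`` of each span.  Inter-chromosomal pairs
    (translocations) use orientation + slop only, since reciprocal overlap
    is undefined across chromosomes.  Orientation '.' on either side of a
    comparison acts as a wildcard when ``require_orientation`` is False.
    """
    for x, y in ((p.a, q.a), (p.b, q.b)):
        if x.chrom != y.chrom:
            return False
        if abs(x.pos - y.pos) > slop:
            return False
        # '.' acts as a wildcard (unoriented database entries)
        if require_orientation and "." not in (x.orient, y.orient) and x.orient != y.orient:
            return False
    if p.intra and q.intra:
        ro = reciprocal_overlap(p.a.pos, p.b.pos, q.a.pos, q.b.pos)
        if ro < reciprocal:
            return False
    elif p.intra != q.intra:
        return False
    return True


def filter_size(pairs: Iterable[BreakpointPair], min_span: int = 500) -> list[BreakpointPair]:
    """Drop intra-chromosomal pairs with span strictly below ``min_span``.

    Translocations have no span and are always kept.
    """
    out = []
    for p in pairs:
        if p.intra and (p.span or 0) < min_span:
            continue
        out.append(p)
    return out


@dataclass
class ConsensusSV:
    """One merged SV cluster with its evidence and filter state."""

    a: Breakend
    b: Breakend
    callers: frozenset[str]
    members: list[BreakpointPair] = field(default_factory=list)
    t_split: int = 0  # max tumor split reads over members
    n_split: int = 0  # max normal split reads over members
    flags: set[str] = field(default_factory=set)
    retained: bool = False
    rescued: bool = False

    @property
    def pair(self) -> BreakpointPair:
        return BreakpointPair(a=self.a, b=self.b)

    @property
    def intra(self) -> bool:
        return self.a.chrom == self.b.chrom

    @property
    def final(self) -> bool:
        return self.retained or self.rescued


def _median_pos(values: Sequence[int]) -> int:
    """Median breakend position; even counts take the lower middle value."""
    vals = sorted(values)
    n = len(vals)
    return vals[(n - 1) // 2]


def merge_svs(
    per_caller: Mapping[str, Sequence[BreakpointPair]],
    slop: int = 300,
    reciprocal: float = 0.5,
) -> list[ConsensusSV]:
    """Single-linkage clustering of one sample's pairs under :func:`match_pairs`.

    The representative pair takes the per-breakend median position of the
    cluster members (ties resolved to the lower coordinate) and the modal
    orientation is the shared one (members match, so orientations agree).
    """
    pairs: list[BreakpointPair] = []
    for caller in sorted(per_caller):
        pairs.extend(per_caller[caller])
    n = len(pairs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if match_pairs(pairs[i], pairs[j], slop=slop, reciprocal=reciprocal):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[BreakpointPair]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(pairs[i])

    out: list[ConsensusSV] = []
    for members in clusters.values():
        rep_a = Breakend(members[0].a.chrom, _median_pos([m.a.pos for m in members]),
                         members[0].a.orient)
        rep_b = Breakend(members[0].b.chrom, _median_pos([m.b.pos for m in members]),
                         members[0].b.orient)
        out.append(
            ConsensusSV(
                a=rep_a,
                b=rep_b,
                callers=frozenset(m.caller for m in members),
                members=sorted(members, key=lambda m: (m.caller, m.a.pos, m.b.pos)),
                t_split=max(m.t_split for m in members),
                n_split=max(m.n_split for m in members),
            )
        )
    out.sort(key=lambda c: (c.a.chrom, c.a.pos, c.b.chrom, c.b.pos))
    return out


def filter_sv_pon_germline(
    consensus: list[ConsensusSV],
    pon_pairs: Sequence[tuple[BreakpointPair, int]],
    germline_db: Sequence[BreakpointPair],
    slop: int = 300,
    reciprocal: float = 0.5,
    pon_min_individuals: int = 2,
) -> list[ConsensusSV]:
    """Flag consensus SVs recurrent in the PON or present in germline SV DBs.

    PON matching uses the full match criteria and requires the PON event in
    >= ``pon_min_individuals`` individuals.  Germline-database entries may
    lack orientation ('.'), which matches any strand.
    """
    for c in consensus:
        rep = c.pair
        for pon_pair, n_indiv in pon_pairs:
            if n_indiv >= pon_min_individuals and match_pairs(
                rep, pon_pair, slop=slop, reciprocal=reciprocal
            ):
                c.flags.add(FLAG_SV_PON)
                break
        for g in germline_db:
            if match_pairs(rep, g, slop=slop, reciprocal=reciprocal):
                c.flags.add(FLAG_SV_GERMLINE)
                break
    return consensus


def apply_sv_retention(
    consensus: list[ConsensusSV],
    changepoints: Sequence[tuple[str, int]],
    changepoint_window: int = 1000,
    min_split_reads: int = 3,
) -> list[ConsensusSV]:
    """Retain unflagged SVs on multi-caller support or orthogonal evidence.

    Single-caller events from the evidence-eligible callers are retained
    when a copy-number changepoint lies within ``changepoint_window`` bp of
    either breakend, or when split-read support is tumor-only (tumor >=
    ``min_split_reads`` and normal == 0).
    """
    cps_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in changepoints:
        cps_by_chrom.setdefault(chrom, []).append(pos)

    def near_changepoint(be: Breakend) -> bool:
        return any(abs(be.pos - p) <= changepoint_window
                   for p in cps_by_chrom.get(be.chrom, ()))

    for c in consensus:
        if c.flags:
            c.retained = False
            continue
        if len(c.callers) >= 2:
            c.retained = True
            continue
        if c.callers & SV_EVIDENCE_CALLERS:
            cnv_support = near_changepoint(c.a) or near_changepoint(c.b)
            split_support = c.t_split >= min_split_reads and c.n_split == 0
            c.retained = cnv_support or split_support
        else:
            c.retained = False
    return consensus


def rescue_svs(
    sample_consensus: Mapping[str, list[ConsensusSV]],
    support: Mapping[str, Sequence[tuple[BreakpointPair, int]]],
    slop: int = 300,
    reciprocal: float = 0.5,
) -> dict[str, list[ConsensusSV]]:
    """Rescue patient-union SVs into samples with non-zero read support.

    An SV retained in one sample but absent from another sample's retained
    set is rescued there iff that sample's supplied read-support table has a
    matching entry with support > 0.  Missing support entries are logged and
    not rescued.  Single-sample patients are returned unchanged.
    """
    samples = sorted(sample_consensus)
    out = {s: list(sample_consensus[s]) for s in samples}
    if len(samples) < 2:
        return out

    union: list[ConsensusSV] = []
    for s in samples:
        for c in sample_consensus[s]:
            if c.retained and not any(
                match_pairs(c.pair, u.pair, slop=slop, reciprocal=reciprocal)
                for u in union
            ):
                union.append(c)

    for s in samples:
        retained = [c for c in sample_consensus[s] if c.retained]
        for u in union:
            if any(match_pairs(u.pair, c.pair, slop=slop, reciprocal=reciprocal)
                   for c in retained):
                continue
            entry = None
            for pair, reads in support.get(s, ()):
                if match_pairs(u.pair, pair, slop=slop, reciprocal=reciprocal):
                    entry = reads
                    break
            if entry is None:
                logger.warning("SV rescue: no read-support entry for %s in %s", u.pair, s)
                continue
            if entry > 0:
                # rescued copy: same representative, no caller support here
                existing = next(
                    (c for c in out[s] if match_pairs(
                        u.pair, c.pair, slop=slop, reciprocal=reciprocal)),
                    None,
                )
                if existing is not None:
                    existing.rescued = True
                else:
                    out[s].append(
                        ConsensusSV(a=u.a, b=u.b, callers=frozenset(),
                                    t_split=entry, rescued=True)
                    )
        out[s].sort(key=lambda c: (c.a.chrom, c.a.pos, c.b.chrom, c.b.pos))
    return out
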