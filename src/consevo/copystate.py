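"""Ploidy-relative copy-number classification and fraction of genome altered.

The copy-neutral state of a sample is defined by its average ploidy: for a
ploidy with fractional part in [0.4, 0.6] (e.g. 3.5) the neutral set is the
two flanking integers {3, 4}; otherwise it is the single rounded ploidy.
Segments are classified relative to that set, fraction of genome altered
(FGA) is the proportion of covered autosomal bases outside it, and focal
events can be annotated against fixed named loci (the AR enhancer by
default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .config import DEFAULT_LOCI

logger = logging.getLogger("consevo")

CLASS_NEUTRAL = "neutral"
CLASS_GAIN = "gain"
CLASS_AMP = "amplification"
CLASS_DEL = "deletion"
CLASS_LOSS = "loss"


@dataclass(frozen=True)
class CopySegment:
    """Genomic interval (0-based half-open) with integer total copy number."""

    chrom: str
    start: int
    end: int
    cn: int
    major_cn: int | None = None
    minor_cn: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start: {self}")
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FocalEvent:
    segment: CopySegment
    state: str
    labels: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.segment.length

    @property
    def focal(self) -> bool:
        return self.length <= 3_000_000


def neutral_state(ploidy: float, frac_window: tuple[float, float] = (0.4, 0.6)) -> frozenset[int]:
    """Copy numbers considered neutral for the given average ploidy.

    Fractional part within ``frac_window`` (inclusive) yields the two
    flanking integers; otherwise the rounded ploidy (round-half-up, so 2.5
    just outside a narrowed window would round to 3 — with the default
    window every half-integer ploidy takes the two-state branch).
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    # round the fractional part so a ploidy like 2.4 (stored as 2.3999...96)
    # still hits the inclusive window boundary
    frac = round(ploidy - math.floor(ploidy), 9)
    lo, hi = frac_window
    if lo <= frac <= hi:
        return frozenset({math.floor(ploidy), math.ceil(ploidy)})
    return frozenset({int(math.floor(ploidy + 0.5))})


def classify_copy_state(cn: int, ploidy: float,
                        frac_window: tuple[float, float] = (0.4, 0.6)) -> str:
    """Classify one integer copy number relative to the neutral state.

    Losses (cn == 0) take precedence over deletions; gains above twice the
    ploidy (strictly) are amplifications.
    """
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    neutral = neutral_state(ploidy, frac_window)
    if cn in neutral:
        return CLASS_NEUTRAL
    if cn == 0:
        return CLASS_LOSS
    if cn < min(neutral):
        return CLASS_DEL
    if cn > 2 * ploidy:
        return CLASS_AMP
    return CLASS_GAIN


def classify_segments(segments: Iterable[CopySegment], ploidy: float,
                      frac_window: tuple[float, float] = (0.4, 0.6)) -> list[FocalEvent]:
    return [
        FocalEvent(segment=s, state=classify_copy_state(s.cn, ploidy, frac_window))
        for s in segments
    ]


def fga(segments: Iterable[CopySegment], neutral: frozenset[int] | set[int],
        autosomes: Sequence[str]) -> float:
    """Fraction of covered autosomal bases whose CN is outside ``neutral``.

    Bases not covered by any segment are excluded from the denominator;
    sex chromosomes are excluded entirely.
    """
    autoset = set(autosomes)
    covered = 0
    altered = 0
    for s in segments:
        if s.chrom not in autoset:
            continue
        covered += s.length
        if s.cn not in neutral:
            altered += s.length
    if covered == 0:
        raise ValueError("no autosomal coverage; FGA undefined")
    return altered / covered


def changepoints_from_segments(segments: Sequence[CopySegment]) -> list[tuple[str, int]]:
    """Copy-number changepoints: boundaries between adjacent segments of
    differing CN, as 1-based positions."""
    out: list[tuple[str, int]] = []
    by_chrom: dict[str, list[CopySegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if prev.end == cur.start and prev.cn != cur.cn:
                out.append((chrom, cur.start + 1))
    return out


def annotate_fixed_loci(
    events: Iterable[FocalEvent],
    loci: Sequence[tuple[str, int, int, str]] = DEFAULT_LOCI,
) -> list[FocalEvent]:
    """Label events with the named loci they overlap.

    Gains/amplifications overlapping a locus get an additional
    ``"<name> gain"`` label (e.g. "AR_enhancer gain"); other states are
    labelled with the plain overlap only.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in loci:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)

    out: list[FocalEvent] = []
    for ev in events:
        tree = trees.get(ev.segment.chrom)
        labels: list[str] = []
        if tree is not None:
            for hit in sorted(tree.overlap(ev.segment.start, ev.segment.end),
                              key=lambda h: (h.begin, h.end)):
                labels.append(hit.data)
                if ev.state in (CLASS_GAIN, CLASS_AMP):
                    labels.append(f"{hit.data} gain")
        out.append(FocalEvent(segment=ev.segment, state=ev.state, labels=tuple(labels)))
    return out
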