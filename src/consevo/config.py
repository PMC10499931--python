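"""Pipeline-wide thresholds and fixed genomic annotations.

Every filter threshold used downstream lives in :class:`Thresholds` so that a
single object can be threaded through the consensus, SV, copy-state and
clonality stages (and overridden from a YAML run config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

logger = logging.getLogger("consevo")


@dataclass(frozen=True)
class Thresholds:
    """Filtering and classification thresholds.

    Defaults encode the post-calling filter set for tumor/normal WGS
    ensemble calling: PON recurrence, population allele frequency, VAF and
    depth cut-offs for small variants; slop / reciprocal-overlap / size /
    evidence rules for SVs; the ploidy window defining the copy-neutral
    state; and the clonality proxy threshold.
    """

    # -- small variants -------------------------------------------------
    pon_min_individuals: int = 2        # PON hit in >= this many normals
    max_population_af: float = 0.01     # MAF >= 1% in any source => germline
    min_tumor_vaf: float = 1e-4
    max_normal_vaf: float = 0.2
    min_depth: int = 2                  # tumor and normal, independently
    pileup_indel_max_len: int = 10      # indels shorter than this use pileup
    caller_count_order: tuple[str, ...] = ("strelka2", "mutect2", "lancet")

    # -- structural variants --------------------------------------------
    sv_slop: int = 300                  # bp, per breakend
    sv_reciprocal: float = 0.5          # reciprocal span overlap, intra-chrom
    sv_min_span: int = 500              # spans strictly below are dropped
    sv_min_split_reads: int = 3         # tumor-only split-read evidence
    sv_changepoint_window: int = 1000   # bp from breakend to CNV changepoint

    # -- copy state ------------------------------------------------------
    ploidy_frac_window: tuple[float, float] = (0.4, 0.6)
    focal_max_len: int = 3_000_000      # focal event size cap, bp

    # -- clonality -------------------------------------------------------
    clonal_ci_threshold: float = 0.9    # CCF CI upper bound for "clonal"
    ccf_ci_level: float = 0.95          # Wilson interval coverage

    def __post_init__(self) -> None:
        if not (0 <= self.max_population_af <= 1):
            raise ValueError("max_population_af must be in [0, 1]")
        if not (0 <= self.min_tumor_vaf <= 1) or not (0 <= self.max_normal_vaf <= 1):
            raise ValueError("VAF thresholds must be in [0, 1]")
        if self.sv_slop < 0 or not (0 <= self.sv_reciprocal <= 1):
            raise ValueError("invalid SV match thresholds")
        lo, hi = self.ploidy_frac_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ploidy_frac_window must be an interval within [0, 1]")
        if not (0 < self.clonal_ci_threshold <= 2):
            raise ValueError("clonal_ci_threshold out of range")

    def replace(self, **kwargs) -> "Thresholds":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kwargs)
        return Thresholds(**vals)


DEFAULT_THRESHOLDS = Thresholds()

# Callers by variant class they contribute to.
SMALLVAR_CALLERS = ("mutect2", "strelka2", "lancet", "svaba")
SV_CALLERS = ("manta", "lumpy", "svaba")
#: callers whose single-caller SV calls can be retained with extra evidence
SV_EVIDENCE_CALLERS = frozenset({"manta", "lumpy"})

#: Androgen-receptor enhancer, GRCh38, 0-based half-open.  Copy gain of this
#: regulatory interval is a recurrent driver in castration-resistant prostate
#: cancer; shipped as the default named locus for event annotation.
AR_ENHANCER_GRCH38: tuple[str, int, int, str] = ("chrX", 66_880_157, 66_935_158, "AR_enhancer")

DEFAULT_LOCI: tuple[tuple[str, int, int, str], ...] = (AR_ENHANCER_GRCH38,)
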