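"""Readers and writers for the pipeline's file formats.

Small-variant call sets travel as minimal somatic VCFs (1-based, one ALT per
record, caller and counts in INFO), SV call sets and SV databases as BEDPE
(0-based half-open one-base breakend intervals), and everything else as TSV.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .smallvar import Pileup, VariantCall, VariantKey
from .sv import Breakend, BreakpointPair

logger = logging.getLogger("consevo")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_INFO_HEADER = [
    '##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling algorithm">',
    '##INFO=<ID=TALT,Number=1,Type=Integer,Description="Tumor alt read pairs">',
    '##INFO=<ID=TREF,Number=1,Type=Integer,Description="Tumor ref read pairs">',
    '##INFO=<ID=NALT,Number=1,Type=Integer,Description="Normal alt read pairs">',
    '##INFO=<ID=NREF,Number=1,Type=Integer,Description="Normal ref read pairs">',
]


def write_caller_vcf(calls: pd.DataFrame, path: str | Path,
                     contigs: Iterable[tuple[str, int]]) -> None:
    """Write one sample+caller call set as a minimal VCF.

    ``calls`` columns: chrom, pos, vid, ref, alt, t_alt, t_ref, n_alt,
    n_ref, caller.  Missing counts (NaN/None) are omitted from INFO.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in contigs]
    lines += _VCF_INFO_HEADER
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = calls.sort_values(["chrom", "pos", "ref", "alt"])
    for row in rows.itertuples(index=False):
        info = [f"CALLER={row.caller}"]
        for tag, value in (("TALT", row.t_alt), ("TREF", row.t_ref),
                           ("NALT", row.n_alt), ("NREF", row.n_ref)):
            if value is not None and not (isinstance(value, float) and math.isnan(value)):
                info.append(f"{tag}={int(value)}")
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.vid}\t{row.ref}\t{row.alt}\t.\tPASS\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_caller_vcf(path: str | Path, sample: str, caller: str) -> list[VariantCall]:
    """Parse a per-caller VCF into :class:`VariantCall` records."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info

            def grab(tag: str) -> int | None:
                return int(info[tag]) if tag in info else None

            for alt in rec.alts or ():
                calls.append(
                    VariantCall(
                        sample=sample, chrom=rec.chrom, pos=rec.pos,
                        ref=rec.ref, alt=alt, caller=caller,
                        t_alt=grab("TALT"), t_ref=grab("TREF"),
                        n_alt=grab("NALT"), n_ref=grab("NREF"),
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def write_bedpe(pairs: pd.DataFrame, path: str | Path,
                extra: list[str] | None = None) -> None:
    """Write breakpoint pairs as BEDPE (0-based half-open breakend intervals).

    Expects 1-based positions in columns pos1/pos2; optional per-row extras
    (e.g. split-read counts) follow the ten standard columns.
    """
    extra = extra or [c for c in ("svid", "t_split", "n_split", "support")
                      if c in pairs.columns]
    rows = pairs.sort_values(["chrom1", "pos1", "chrom2", "pos2"])
    lines = []
    for i, row in enumerate(rows.itertuples(index=False)):
        name = getattr(row, "svid", f"bp{i + 1}")
        fields = [row.chrom1, str(row.pos1 - 1), str(row.pos1),
                  row.chrom2, str(row.pos2 - 1), str(row.pos2),
                  str(name), ".", row.strand1, row.strand2]
        fields += [str(getattr(row, c)) for c in extra if c != "svid"]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedpe(path: str | Path, sample: str = "", caller: str = "",
               n_extra_ints: int = 0) -> list[tuple[BreakpointPair, tuple[int, ...]]]:
    """Parse BEDPE into canonical :class:`BreakpointPair` records.

    Returns (pair, extras) tuples where extras are the first
    ``n_extra_ints`` integer columns after the standard ten.
    """
    out: list[tuple[BreakpointPair, tuple[int, ...]]] = []
    text = Path(path).read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        pair = BreakpointPair(
            a=Breakend(f[0], int(f[2]), f[8]),   # end1 is the 1-based breakend
            b=Breakend(f[3], int(f[5]), f[9]),
            sample=sample, caller=caller,
        )
        extras = tuple(int(x) for x in f[10:10 + n_extra_ints])
        out.append((pair, extras))
    return out


# ---------------------------------------------------------------------------
# TSV table loaders
# ---------------------------------------------------------------------------

def load_pileup(path: str | Path) -> Pileup:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    pile = Pileup()
    for row in df.itertuples(index=False):
        pile.add(row.sample, row.tissue, row.chrom, int(row.pos), row.allele,
                 int(row.count), int(row.depth))
    return pile


def load_pon_snv(path: str | Path) -> dict[VariantKey, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {(r.chrom, int(r.pos), r.ref, r.alt): int(r.n_individuals)
            for r in df.itertuples(index=False)}


def load_population_af(path: str | Path) -> dict[VariantKey, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): {"1000g": float(r.kg_af),
                                              "gnomad": float(r.gnomad_af)}
        for r in df.itertuples(index=False)
    }


def load_key_set(path: str | Path) -> dict[str, set[VariantKey]]:
    """Per-sample variant-identity sets (lancet validation / Manta small SVs)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, set[VariantKey]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.sample, set()).add((r.chrom, int(r.pos), r.ref, r.alt))
    return out


def load_segments(path: str | Path):
    from .copystate import CopySegment

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[CopySegment]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.sample, []).append(
            CopySegment(chrom=r.chrom, start=int(r.start), end=int(r.end),
                        cn=int(r.cn),
                        major_cn=int(r.major_cn) if not pd.isna(r.major_cn) else None,
                        minor_cn=int(r.minor_cn) if not pd.isna(r.minor_cn) else None)
        )
    return out


def load_sv_support(path: str | Path) -> dict[str, list[tuple[BreakpointPair, int]]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    out: dict[str, list[tuple[BreakpointPair, int]]] = {}
    for r in df.itertuples(index=False):
        pair = BreakpointPair(a=Breakend(r.chrom1, int(r.pos1), r.strand1),
                              b=Breakend(r.chrom2, int(r.pos2), r.strand2))
        out.setdefault(r.sample, []).append((pair, int(r.support)))
    return out


def load_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "patient": str})
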