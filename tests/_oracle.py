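"""Independent brute-force re-implementation of every filter rule.

Reads the raw cohort files directly (plain line/csv parsing, no shared code
with the package) and re-derives, per record, the merged identity, caller
support, chosen counts, filter flags, retention and rescue.  Used as the
ground-truth comparator for the pipeline's retained+rescued sets.
"""

from __future__ import annotations

import csv
import statistics
from pathlib import Path

SMALL_CALLERS = ["mutect2", "strelka2", "lancet", "svaba"]
SV_CALLERS = ["manta", "lumpy", "svaba"]


def _read_tsv(path):
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _trim(chrom, pos, ref, alt):
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return chrom, pos, ref, alt


def _parse_vcf(path):
    records = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        chrom, pos, _vid, ref, alt, _q, _f, info = line.split("\t")[:8]
        tags = dict(kv.split("=") for kv in info.split(";") if "=" in kv)
        counts = {k: int(tags[k]) for k in ("TALT", "TREF", "NALT", "NREF")
                  if k in tags}
        records.append((chrom, int(pos), ref, alt, counts))
    return records


def oracle_smallvar(cohort_dir):
    """Final (retained or rescued) small-variant sets, per sample.

    Returns {sample: {key: (retained, rescued)}} with key =
    (chrom, pos, ref, alt) after trimming.
    """
    cohort_dir = Path(cohort_dir)
    samples = _read_tsv(cohort_dir / "samples.tsv")
    by_patient = {}
    for row in samples:
        by_patient.setdefault(row["patient"], []).append(row["sample"])

    pile = {}
    for row in _read_tsv(cohort_dir / "pileups.tsv"):
        pile[(row["sample"], row["tissue"], row["chrom"], int(row["pos"]),
              row["allele"])] = (int(row["count"]), int(row["depth"]))
    pon = {(r["chrom"], int(r["pos"]), r["ref"], r["alt"]): int(r["n_individuals"])
           for r in _read_tsv(cohort_dir / "pon_snv.tsv")}
    af = {(r["chrom"], int(r["pos"]), r["ref"], r["alt"]):
          max(float(r["kg_af"]), float(r["gnomad_af"]))
          for r in _read_tsv(cohort_dir / "population_af.tsv")}
    lval, msv = {}, {}
    for r in _read_tsv(cohort_dir / "lancet_validation.tsv"):
        lval.setdefault(r["sample"], set()).add(
            (r["chrom"], int(r["pos"]), r["ref"], r["alt"]))
    for r in _read_tsv(cohort_dir / "manta_smallsv.tsv"):
        msv.setdefault(r["sample"], set()).add(
            (r["chrom"], int(r["pos"]), r["ref"], r["alt"]))

    retained_sets = {}
    merged_all = {}
    for row in samples:
        sample = row["sample"]
        # 1. load + split MNVs + trim
        support, parents, caller_counts = {}, {}, {}
        for caller in SMALL_CALLERS:
            path = cohort_dir / "calls" / f"{sample}.{caller}.vcf"
            if not path.exists():
                continue
            for chrom, pos, ref, alt, counts in _parse_vcf(path):
                if len(ref) == len(alt) and len(ref) > 1:
                    parent = (chrom, pos, ref, alt)
                    for i in range(len(ref)):
                        if ref[i] == alt[i]:
                            continue
                        key = (chrom, pos + i, ref[i], alt[i])
                        support.setdefault(key, set()).add(caller)
                        parents.setdefault(key, set()).add(parent)
                        caller_counts.setdefault(key, {})[caller] = counts
                else:
                    key = _trim(chrom, pos, ref, alt)
                    support.setdefault(key, set()).add(caller)
                    caller_counts.setdefault(key, {})[caller] = counts
        # 2. re-fuse MNVs with uniform support
        fused, consumed = {}, set()
        for parent in sorted({p for ps in parents.values() for p in ps}):
            chrom, pos, ref, alt = parent
            keys = [(chrom, pos + i, ref[i], alt[i])
                    for i in range(len(ref)) if ref[i] != alt[i]]
            if not all(k in support for k in keys):
                continue
            if len({frozenset(support[k]) for k in keys}) != 1:
                continue
            fused[parent] = set(support[keys[0]])
            consumed.update(keys)
        variants = {}
        for key in support:
            if key not in consumed:
                variants[key] = set(support[key])
        for parent, callers in fused.items():
            chrom, pos, ref, alt = parent
            variants[parent] = callers
            # counts of the first constituent stand for the whole MNV
            first = next((chrom, pos + i, ref[i], alt[i])
                         for i in range(len(ref)) if ref[i] != alt[i])
            caller_counts[parent] = caller_counts.get(first, {})
        # 3. choose counts, 4. flags, 5. retention
        decided = {}
        for key in sorted(variants):
            chrom, pos, ref, alt = key
            callers = variants[key]
            is_indel = len(ref) != len(alt)
            is_delins = is_indel and len(ref) > 1 and len(alt) > 1
            length = max(len(ref), len(alt)) - 1
            counts = None
            if (not is_indel) or (not is_delins and length < 10):
                ta = pile.get((sample, "tumor", chrom, pos, alt))
                tr = pile.get((sample, "tumor", chrom, pos, ref))
                na = pile.get((sample, "normal", chrom, pos, alt))
                nr = pile.get((sample, "normal", chrom, pos, ref))
                if None not in (ta, tr, na, nr):
                    counts = (ta[0], tr[0], na[0], nr[0])
            else:
                for caller in ("strelka2", "mutect2", "lancet"):
                    cc = caller_counts.get(key, {}).get(caller)
                    if cc and all(t in cc for t in ("TALT", "TREF", "NALT", "NREF")):
                        counts = (cc["TALT"], cc["TREF"], cc["NALT"], cc["NREF"])
                        break
            flagged = False
            if pon.get(key, 0) >= 2:
                flagged = True
            if af.get(key, 0.0) >= 0.01:
                flagged = True
            if counts is not None:
                t_alt, t_ref, n_alt, n_ref = counts
                td, nd = t_alt + t_ref, n_alt + n_ref
                tv = t_alt / td if td else 0.0
                nv = n_alt / nd if nd else 0.0
                if tv < 0.0001 or nv > 0.2 or td < 2 or nd < 2 or nv > tv:
                    flagged = True
            valid = key in lval.get(sample, set()) or key in msv.get(sample, set())
            retained = (not flagged) and (len(callers) >= 2
                                          or (len(callers) == 1 and valid))
            decided[key] = retained
        retained_sets[sample] = {k for k, r in decided.items() if r}
        merged_all[sample] = decided

    # 6. rescue across each patient's samples
    out = {}
    for patient, names in by_patient.items():
        union = set()
        for s in names:
            union |= retained_sets[s]
        for s in names:
            final = {k: (True, False) for k in retained_sets[s]}
            if len(names) >= 2:
                for key in union - retained_sets[s]:
                    chrom, pos, ref, alt = key
                    ta = pile.get((s, "tumor", chrom, pos, alt))
                    tr = pile.get((s, "tumor", chrom, pos, ref))
                    if ta is None or tr is None:
                        continue
                    if (ta[0] + tr[0]) > 0 and ta[0] > 0:
                        final[key] = (False, True)
            out[s] = final
    return out


# ---------------------------------------------------------------------------
# SVs
# ---------------------------------------------------------------------------

def _read_bedpe(path, n_extra=0):
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        pair = (f[0], int(f[2]), f[8], f[3], int(f[5]), f[9])
        rows.append((pair, tuple(int(x) for x in f[10:10 + n_extra])))
    return rows


def _pair_match(p, q, slop=300, recip=0.5):
    c1, p1, s1, c2, p2, s2 = p
    d1, q1, t1, d2, q2, t2 = q
    if c1 != d1 or c2 != d2:
        return False
    if abs(p1 - q1) > slop or abs(p2 - q2) > slop:
        return False
    for a, b in ((s1, t1), (s2, t2)):
        if a != "." and b != "." and a != b:
            return False
    p_intra, q_intra = c1 == c2, d1 == d2
    if p_intra != q_intra:
        return False
    if p_intra:
        la, lb = p2 - p1, q2 - q1
        if la <= 0 or lb <= 0:
            return False
        ov = min(p2, q2) - max(p1, q1)
        if ov <= 0 or min(ov / la, ov / lb) < recip:
            return False
    return True


def oracle_sv(cohort_dir):
    """Final SV sets per sample: {sample: {rep_pair: (retained, rescued)}}."""
    cohort_dir = Path(cohort_dir)
    samples = _read_tsv(cohort_dir / "samples.tsv")
    by_patient = {}
    for row in samples:
        by_patient.setdefault(row["patient"], []).append(row["sample"])

    pon = _read_bedpe(cohort_dir / "pon_sv.bedpe", n_extra=1)
    germ = [p for p, _ in _read_bedpe(cohort_dir / "germline_sv.bedpe")]
    support = {}
    for r in _read_tsv(cohort_dir / "sv_support.tsv"):
        key = (r["chrom1"], int(r["pos1"]), r["strand1"],
               r["chrom2"], int(r["pos2"]), r["strand2"])
        support.setdefault(r["sample"], []).append((key, int(r["support"])))
    segs = {}
    for r in _read_tsv(cohort_dir / "segments.tsv"):
        segs.setdefault(r["sample"], []).append(
            (r["chrom"], int(r["start"]), int(r["end"]), int(r["cn"])))

    def changepoints(sample):
        cps = []
        rows = sorted(segs[sample])
        for a, b in zip(rows, rows[1:]):
            if a[0] == b[0] and a[2] == b[1] and a[3] != b[3]:
                cps.append((a[0], b[1] + 1))
        return cps

    retained_sets = {}
    for row in samples:
        sample = row["sample"]
        calls = []  # (pair, caller, t_split, n_split)
        for caller in SV_CALLERS:
            path = cohort_dir / "sv_calls" / f"{sample}.{caller}.bedpe"
            if not path.exists():
                continue
            for pair, extras in _read_bedpe(path, n_extra=2):
                c1, p1, s1, c2, p2, s2 = pair
                if c1 == c2 and (p2 - p1) < 500:
                    continue  # size filter
                calls.append((pair, caller, extras[0], extras[1]))
        # transitive closure clustering, brute force to fixpoint
        clusters = [[c] for c in calls]
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(_pair_match(a[0], b[0])
                           for a in clusters[i] for b in clusters[j]):
                        clusters[i].extend(clusters[j])
                        del clusters[j]
                        changed = True
                        break
                if changed:
                    break
        consensus = []
        for members in clusters:
            p1s = sorted(m[0][1] for m in members)
            p2s = sorted(m[0][4] for m in members)
            rep = (members[0][0][0], p1s[(len(p1s) - 1) // 2], members[0][0][2],
                   members[0][0][3], p2s[(len(p2s) - 1) // 2], members[0][0][5])
            callers = {m[1] for m in members}
            t_split = max(m[2] for m in members)
            n_split = max(m[3] for m in members)
            consensus.append((rep, callers, t_split, n_split))
        cps = changepoints(sample)
        final = {}
        for rep, callers, t_split, n_split in consensus:
            flagged = any(n >= 2 and _pair_match(rep, p) for p, (n,) in pon)
            flagged = flagged or any(_pair_match(rep, g) for g in germ)
            if flagged:
                final[rep] = False
                continue
            if len(callers) >= 2:
                final[rep] = True
            elif callers & {"manta", "lumpy"}:
                near = any(
                    (c == rep[0] and abs(p - rep[1]) <= 1000)
                    or (c == rep[3] and abs(p - rep[4]) <= 1000)
                    for c, p in cps
                )
                final[rep] = near or (t_split >= 3 and n_split == 0)
            else:
                final[rep] = False
        retained_sets[sample] = final

    out = {}
    for patient, names in by_patient.items():
        union = []
        for s in names:
            for rep, r in retained_sets[s].items():
                if r and not any(_pair_match(rep, u) for u in union):
                    union.append(rep)
        for s in names:
            final = {rep: (True, False)
                     for rep, r in retained_sets[s].items() if r}
            if len(names) >= 2:
                for u in union:
                    if any(_pair_match(u, rep) for rep in final):
                        continue
                    entry = next((v for p, v in support.get(s, [])
                                  if _pair_match(u, p)), None)
                    if entry is not None and entry > 0:
                        existing = next(
                            (rep for rep, r in retained_sets[s].items()
                             if _pair_match(u, rep)), None)
                        final[existing if existing is not None else u] = (False, True)
            out[s] = final
    return out
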