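"""Continuous high-confidence regions (CHCRs) and the final benchmark set.

A benchmark SV is a high-confidence SV additionally supported by at least
one haplotype assembly. CHCR construction starts from the haplotype
coverage tracks (union of paternal and maternal by default), then splits
candidate regions at every high-confidence SV *lacking* haplotype support,
excising a +/-flank window around it; surviving sub-regions shorter than
``min_region`` are dropped. The benchmark then enumerates, inside each
CHCR, every supported SV — within a CHCR the benchmark claims completeness,
so calls there can be judged true or false.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import read_sv_vcf, write_bed, write_sv_vcf
from .matching import MatchParams, SVMERGE_DEFAULT, find_match
from .model import Callset, RegionSet, SVRecord


@dataclass
class CHCR:
    """One continuous high-confidence interval with its benchmark SVs."""

    chrom: str
    start: int
    end: int
    sv_ids: set = field(default_factory=set)
    hap: set = field(default_factory=set)

    def contains(self, rec: SVRecord) -> bool:
        s, e = rec.span()
        return rec.chrom == self.chrom and self.start <= s and e <= self.end


@dataclass
class BenchmarkSet:
    """CHCRs plus the benchmark SVs they contain (hap_support non-empty)."""

    chcrs: list
    svs: Callset

    def regions(self) -> RegionSet:
        return RegionSet([(c.chrom, c.start, c.end) for c in self.chcrs], "chcr").normalize()

    def validate(self) -> None:
        by_id = {r.id: r for r in self.svs}
        seen: set = set()
        for c in self.chcrs:
            if c.start >= c.end:
                raise ValueError(f"empty CHCR {c.chrom}:{c.start}-{c.end}")
            if not c.hap:
                raise ValueError(f"CHCR {c.chrom}:{c.start}-{c.end} has no haplotype coverage")
            for sid in c.sv_ids:
                if sid in seen:
                    raise ValueError(f"SV {sid} in more than one CHCR")
                seen.add(sid)
                if not c.contains(by_id[sid]):
                    raise ValueError(f"SV {sid} outside its CHCR")
        for rec in self.svs:
            if not rec.hap_support:
                raise ValueError(f"benchmark SV {rec.id} lacks haplotype support")
            if rec.id not in seen:
                raise ValueError(f"benchmark SV {rec.id} assigned to no CHCR")


def annotate_hap_support(
    highconf: Callset,
    pat_calls: Callset,
    mat_calls: Callset,
    p: MatchParams = SVMERGE_DEFAULT,
) -> Callset:
    """Mark each high-confidence SV with the haplotype assemblies that confirm it."""
    pat_idx = pat_calls.starts_by_chrom()
    mat_idx = mat_calls.starts_by_chrom()
    out = []
    for rec in highconf:
        r = rec.copy()
        r.hap_support = set()
        if find_match(r, pat_idx, p) is not None:
            r.hap_support.add("paternal")
        if find_match(r, mat_idx, p) is not None:
            r.hap_support.add("maternal")
        out.append(r)
    return Callset(highconf.label, out, dict(highconf.meta)).sort()


def build_chcrs(
    annotated: Callset,
    pat_cov: RegionSet,
    mat_cov: RegionSet,
    flank: int = 1000,
    min_region: int = 10_000,
    coverage_mode: str = "union",
) -> BenchmarkSet:
    """Carve CHCRs out of haplotype coverage and collect the benchmark SVs.

    ``coverage_mode`` selects how the two haplotype coverage tracks combine
    into candidate regions ('union' or 'intersection'). Unsupported
    high-confidence SVs (empty hap_support) each excise a window of
    +/-``flank`` bp around their span from the candidate regions.
    """
    if coverage_mode == "union":
        candidate = pat_cov.union(mat_cov)
    elif coverage_mode == "intersection":
        candidate = pat_cov.intersection(mat_cov)
    else:
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")

    cuts = []
    for rec in annotated:
        if not rec.hap_support:
            e = rec.end if rec.svtype == "DEL" else rec.start
            lo, hi = max(0, rec.start - flank), e + flank
            if hi > lo:
                cuts.append((rec.chrom, lo, hi))
    surviving = candidate.subtract(RegionSet(cuts)) if cuts else candidate
    surviving = RegionSet(
        [(c, s, e) for c, s, e in surviving.intervals if e - s >= min_region]
    )

    pat_n = pat_cov.normalize()
    mat_n = mat_cov.normalize()
    chcrs = []
    for chrom, s, e in surviving.intervals:
        hap = set()
        if pat_n.overlaps(chrom, s, e):
            hap.add("paternal")
        if mat_n.overlaps(chrom, s, e):
            hap.add("maternal")
        chcrs.append(CHCR(chrom, s, e, set(), hap))

    by_chrom: dict = {}
    for i, c in enumerate(chcrs):
        by_chrom.setdefault(c.chrom, []).append(i)
    bench_records = []
    for rec in annotated:
        if not rec.hap_support:
            continue
        for i in by_chrom.get(rec.chrom, []):
            if chcrs[i].contains(rec):
                chcrs[i].sv_ids.add(rec.id)
                bench_records.append(rec.copy())
                break
    svs = Callset("benchmark", bench_records).sort()
    bs = BenchmarkSet(chcrs, svs)
    bs.validate()
    return bs


def emit_benchmark(bs: BenchmarkSet, vcf_path: str, bed_path: str) -> None:
    """Distribute the benchmark as a truth VCF plus a regions BED4.

    The BED name column carries the haplotype coverage of each CHCR;
    ``read_benchmark`` reconstructs the BenchmarkSet from the pair.
    """
    write_sv_vcf(bs.svs, vcf_path)
    rs = RegionSet([(c.chrom, c.start, c.end) for c in bs.chcrs])
    names = ["|".join(sorted(c.hap)) for c in bs.chcrs]
    write_bed(rs, bed_path, names=names)


def read_benchmark(vcf_path: str, bed_path: str) -> BenchmarkSet:
    """Rebuild a BenchmarkSet from the files written by emit_benchmark."""
    svs = read_sv_vcf(vcf_path, "benchmark")
    chcrs = []
    with open(bed_path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            hap = set(fields[3].split("|")) if len(fields) > 3 and fields[3] else set()
            chcrs.append(CHCR(fields[0], int(fields[1]), int(fields[2]), set(), hap))
    by_chrom: dict = {}
    for i, c in enumerate(chcrs):
        by_chrom.setdefault(c.chrom, []).append(i)
    for rec in svs:
        for i in by_chrom.get(rec.chrom, []):
            if chcrs[i].contains(rec):
                chcrs[i].sv_ids.add(rec.id)
                break
    bs = BenchmarkSet(chcrs, svs)
    bs.validate()
    return bs
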