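"""Seeded generators for a synthetic trio test bed.

Everything here is deterministic under its seed: a repeat-bearing random
reference, a diploid trio whose haplotypes carry planted insertions and
deletions (with the mobile-element size peaks near 300 bp and 6 kb that
dominate real insertion/deletion spectra), per-platform corrupted callsets
that emulate the qualitative strengths and weaknesses of the five
platforms, and error-bearing long reads labelled by haplotype of origin.

The generator emulates what the pipeline needs to be exercised end to end
— breakpoint jitter, platform-specific sensitivity by size and type,
spurious calls, substitution sequencing errors, homozygous-identical
("shared") regions that defeat trio-binning. It does not model long-read
homopolymer artifacts, optical-map raw signal, or reference biases; see
the methods note for what that implies about the tests.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chcr import BenchmarkSet, CHCR
from .model import Callset, RegionSet, SVRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _random_seq(rng, n: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def _mutate(rng, seq: str, rate: float) -> str:
    codes = _encode(seq).copy()
    n_mut = rng.binomial(len(codes), rate)
    if n_mut:
        pos = rng.choice(len(codes), size=n_mut, replace=False)
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_mut).astype(np.uint8)) % 4
    return _decode(codes)


def _resize(rng, seq: str, size: int) -> str:
    if len(seq) >= size:
        return seq[:size]
    reps = size // len(seq) + 1
    return (seq * reps)[:size]


# ---------------------------------------------------------------------------
# SV size spectrum

@dataclass(frozen=True)
class SizeComponent:
    weight: float
    dist: str  # "uniform" or "normal"
    a: float  # lo (uniform) or mean (normal)
    b: float  # hi (uniform) or sd (normal)


@dataclass(frozen=True)
class SVSpectrum:
    """Mixture of size components with the SINE-Alu / LINE peaks.

    Defaults: a uniform 50-1000 bp background plus normal components
    centred at 300 bp (Alu-like) and 6 kb (LINE-like). All sampled sizes
    are floored at 50 bp.
    """

    ins_fraction: float = 0.5
    components: tuple = (
        SizeComponent(0.45, "uniform", 50, 1000),
        SizeComponent(0.35, "normal", 300, 30),
        SizeComponent(0.20, "normal", 6000, 400),
    )

    def __post_init__(self):
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, expected 1")

    def sample_sizes(self, rng, n: int) -> np.ndarray:
        weights = np.array([c.weight for c in self.components])
        which = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n, dtype=np.int64)
        for i, comp in enumerate(self.components):
            mask = which == i
            m = int(mask.sum())
            if not m:
                continue
            if comp.dist == "uniform":
                vals = rng.integers(int(comp.a), int(comp.b) + 1, size=m)
            else:
                vals = np.rint(rng.normal(comp.a, comp.b, size=m)).astype(np.int64)
            out[mask] = vals
        return np.maximum(out, 50)


DEFAULT_SPECTRUM = SVSpectrum()


# ---------------------------------------------------------------------------
# Reference with planted mobile-element copies

@dataclass(frozen=True)
class Element:
    start: int
    end: int
    family: str  # "ALU" (~300 bp) or "LINE" (~6 kb)


def simulate_reference(
    length: int,
    gc: float = 0.41,
    element_density: float = 50.0,
    seed: int = 0,
) -> tuple[str, list]:
    """Random reference with planted, lightly mutated element copies.

    ``element_density`` is expected elements per Mb (Poisson); 80% are
    Alu-like 300 bp copies, 20% LINE-like 6 kb copies, drawn from small
    per-run consensus libraries mutated ~2% per copy.
    """
    rng = np.random.default_rng(seed)
    codes = rng.choice(
        4, size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ).astype(np.uint8)
    alu_lib = [_random_seq(rng, 300, gc) for _ in range(3)]
    line_lib = [_random_seq(rng, 6000, gc) for _ in range(2)]
    n_elem = int(rng.poisson(element_density * length / 1e6))
    occupied: list = []  # sorted (start, end)
    elements = []
    for _ in range(n_elem):
        family = "ALU" if rng.random() < 0.8 else "LINE"
        lib = alu_lib if family == "ALU" else line_lib
        size = len(lib[0])
        if length < size + 200:
            continue
        for _attempt in range(50):
            start = int(rng.integers(100, length - size - 100))
            i = bisect_left(occupied, (start, 0))
            prev_ok = i == 0 or occupied[i - 1][1] + 100 <= start
            next_ok = i == len(occupied) or start + size + 100 <= occupied[i][0]
            if prev_ok and next_ok:
                copy = _mutate(rng, lib[int(rng.integers(len(lib)))], 0.02)
                codes[start : start + size] = _encode(copy)
                insort(occupied, (start, start + size))
                elements.append(Element(start, start + size, family))
                break
    elements.sort(key=lambda e: e.start)
    return _decode(codes), elements


# ---------------------------------------------------------------------------
# Trio with planted SVs and SNVs

#: haplotype identifiers: (parent, haplotype index)
_HAPS = (("father", 0), ("father", 1), ("mother", 0), ("mother", 1))


@dataclass
class SimSV:
    """One planted SV in reference coordinates."""

    id: str
    start: int
    svtype: str
    svlen: int
    seq: str  # inserted allele (INS) or deleted reference segment (DEL)
    carriers: frozenset  # subset of _HAPS


@dataclass
class SyntheticTruth:
    """A diploid trio genome with full bookkeeping of the planted variants."""

    chrom: str
    reference: str
    father: tuple
    mother: tuple
    transmitted: dict  # parent -> haplotype index inherited by the child
    truth: Callset  # the child's SVs, reference coordinates
    all_svs: list
    snvs: dict  # (parent, hap) -> list of (pos, base)
    shared_regions: RegionSet
    seed: int

    @property
    def length(self) -> int:
        return len(self.reference)

    @property
    def child_paternal(self) -> str:
        return self.father[self.transmitted["father"]]

    @property
    def child_maternal(self) -> str:
        return self.mother[self.transmitted["mother"]]

    def assembly_callsets(self) -> tuple[Callset, Callset]:
        """SVs an error-free assembly of each child haplotype would report."""
        pat = [r.copy() for r in self.truth if "paternal" in r.hap_support]
        mat = [r.copy() for r in self.truth if "maternal" in r.hap_support]
        for recs, lbl in ((pat, "pat_asm"), (mat, "mat_asm")):
            for r in recs:
                r.support = set()
                r.hap_support = set()
        return Callset("pat_asm", pat).sort(), Callset("mat_asm", mat).sort()

    def coverage_regions(self) -> tuple[RegionSet, RegionSet]:
        full = [(self.chrom, 0, self.length)]
        return RegionSet(list(full), "pat_cov"), RegionSet(list(full), "mat_cov")


def apply_variants(ref: str, snvs, svs) -> str:
    """Apply SNVs then sorted non-overlapping SVs (both in ref coords)."""
    arr = bytearray(ref.encode("ascii"))
    for pos, base in snvs:
        arr[pos] = ord(base)
    pieces = []
    cur = 0
    for sv in sorted(svs, key=lambda s: s.start):
        if sv.start < cur:
            raise ValueError(f"overlapping SVs at {sv.start}")
        pieces.append(bytes(arr[cur : sv.start]))
        if sv.svtype == "DEL":
            cur = sv.start + sv.svlen
        else:
            pieces.append(sv.seq.encode("ascii"))
            cur = sv.start
    pieces.append(bytes(arr[cur:]))
    return b"".join(pieces).decode("ascii")


_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def simulate_trio(
    ref: str,
    sv_count: int,
    spectrum: SVSpectrum = DEFAULT_SPECTRUM,
    snv_rate: float = 1e-3,
    seed: int = 0,
    chrom: str = "chr1",
    shared_frac: float = 0.1,
    elements: list | None = None,
    p_hom_child: float = 0.15,
    p_untransmitted: float = 0.25,
) -> SyntheticTruth:
    """Plant SVs and SNVs on four parental haplotypes; child inherits one of each.

    The first ``shared_frac`` of the reference receives no variants at all,
    producing a homozygous-identical region across the whole trio (reads
    from there are expected to stay unassigned in trio-binning). Each SV is
    carried by the child heterozygously (one transmitted haplotype), or
    homozygously with probability ``p_hom_child``, or only by untransmitted
    haplotypes with probability ``p_untransmitted`` (absent from the child).
    Peak-size deletions snap onto unused planted elements when an element
    annotation is supplied, tying the size peaks to the element copies.
    """
    rng = np.random.default_rng(seed)
    length = len(ref)
    margin = 800
    shared_end = int(shared_frac * length)
    zone_lo, zone_hi = shared_end + margin, length - margin

    alu_lib = [_random_seq(rng, 300) for _ in range(2)]
    line_lib = [_random_seq(rng, 6000) for _ in range(2)]
    free_elements = {
        "ALU": [e for e in (elements or []) if e.family == "ALU" and e.start >= zone_lo],
        "LINE": [e for e in (elements or []) if e.family == "LINE" and e.start >= zone_lo],
    }

    occupied: list = []  # sorted (start, end) including margin

    def is_free(start: int, span: int) -> bool:
        i = bisect_left(occupied, (start, 0))
        prev_ok = i == 0 or occupied[i - 1][1] + margin <= start
        next_ok = i == len(occupied) or start + span + margin <= occupied[i][0]
        return prev_ok and next_ok

    sizes = spectrum.sample_sizes(rng, sv_count)
    svs: list[SimSV] = []
    for i in range(sv_count):
        svtype = "INS" if rng.random() < spectrum.ins_fraction else "DEL"
        size = int(sizes[i])
        start = None
        if svtype == "DEL":
            family = (
                "ALU" if abs(size - 300) <= 30 else "LINE" if abs(size - 6000) <= 600 else None
            )
            if family and free_elements[family]:
                # snap the deletion onto a planted element copy
                for j, el in enumerate(free_elements[family]):
                    if el.end <= zone_hi and is_free(el.start, el.end - el.start):
                        start, size = el.start, el.end - el.start
                        free_elements[family].pop(j)
                        break
        if start is None:
            span = size if svtype == "DEL" else 0
            for _attempt in range(200):
                cand = int(rng.integers(zone_lo, zone_hi - span))
                if is_free(cand, span):
                    start = cand
                    break
        if start is None:
            raise ValueError("could not place all SVs: reference too crowded")

        if svtype == "DEL":
            seq = ref[start : start + size]
        elif abs(size - 300) <= 60:
            seq = _mutate(rng, _resize(rng, alu_lib[int(rng.integers(2))], size), 0.02)
        elif abs(size - 6000) <= 1200:
            seq = _mutate(rng, _resize(rng, line_lib[int(rng.integers(2))], size), 0.02)
        else:
            seq = _random_seq(rng, size)

        r = rng.random()
        if r < p_untransmitted:
            parent = "father" if rng.random() < 0.5 else "mother"
            carriers = frozenset({(parent, 1)})  # haplotype 1 is never transmitted
        elif r < p_untransmitted + p_hom_child:
            carriers = frozenset({("father", 0), ("mother", 0)})
        else:
            parent = "father" if rng.random() < 0.5 else "mother"
            carriers = frozenset({(parent, 0)})
        span = size if svtype == "DEL" else 0
        insort(occupied, (start, start + span))
        svs.append(SimSV(f"sv{i:05d}", start, svtype, size, seq, carriers))

    # per-haplotype SNVs outside the shared region
    snvs: dict = {}
    for hap in _HAPS:
        pos = np.flatnonzero(rng.random(length) < snv_rate)
        pos = pos[pos >= shared_end]
        snvs[hap] = [(int(p), rng.choice(list(_OTHER[ref[p]]))) for p in pos]

    haplotypes = {
        hap: apply_variants(ref, snvs[hap], [sv for sv in svs if hap in sv.carriers])
        for hap in _HAPS
    }

    transmitted = {"father": 0, "mother": 0}
    child_records = []
    for sv in svs:
        hap_support = set()
        if ("father", 0) in sv.carriers:
            hap_support.add("paternal")
        if ("mother", 0) in sv.carriers:
            hap_support.add("maternal")
        if not hap_support:
            continue
        child_records.append(
            SVRecord(
                id=sv.id,
                chrom=chrom,
                start=sv.start,
                svtype=sv.svtype,
                svlen=sv.svlen,
                alt_seq=sv.seq if sv.svtype == "INS" else "",
                ref_seq=sv.seq if sv.svtype == "DEL" else "",
                hap_support=hap_support,
                genotype="hom" if len(hap_support) == 2 else "het",
            )
        )
    truth = Callset("truth", child_records).sort()
    shared = RegionSet([(chrom, 0, shared_end)] if shared_end else [], "shared")
    return SyntheticTruth(
        chrom=chrom,
        reference=ref,
        father=(haplotypes[("father", 0)], haplotypes[("father", 1)]),
        mother=(haplotypes[("mother", 0)], haplotypes[("mother", 1)]),
        transmitted=transmitted,
        truth=truth,
        all_svs=svs,
        snvs=snvs,
        shared_regions=shared,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Platform callset corruption

@dataclass(frozen=True)
class PlatformProfile:
    """Detection behaviour of one platform/caller.

    ``rules`` are (svtype, min_size, max_size, prob) overrides checked in
    order before the per-type base sensitivities; jitter and length error
    are normal with the given sd (bp); ``fp_rate`` is expected spurious
    calls per Mb. These defaults are free parameters chosen to reproduce
    the qualitative platform contrasts (CCS/CLR miss long insertions,
    ONT favours deletions over insertions, optical mapping is blind below
    1 kb and coarse at breakpoints); they are config values, not claims.
    """

    label: str
    sens_del: float = 0.9
    sens_ins: float = 0.9
    rules: tuple = ()
    jitter_sd: float = 10.0
    len_sd: float = 5.0
    fp_rate: float = 5.0
    emits_sequence: bool = True

    def sensitivity(self, svtype: str, size: int) -> float:
        for rtype, lo, hi, prob in self.rules:
            if (rtype in ("*", svtype)) and lo <= size < hi:
                return prob
        return self.sens_del if svtype == "DEL" else self.sens_ins


_INF = float("inf")

DEFAULT_PROFILES = (
    PlatformProfile("CCS", 0.95, 0.95, (("INS", 5000, _INF, 0.20),), 5, 2, 5, True),
    PlatformProfile("CLR", 0.90, 0.88, (("INS", 5000, _INF, 0.25),), 20, 10, 8, True),
    PlatformProfile("ONT", 0.92, 0.75, (), 30, 15, 8, True),
    PlatformProfile("ASM", 0.85, 0.85, (), 2, 1, 3, True),
    PlatformProfile("BN", 0.80, 0.80, (("*", 0, 1000, 0.0),), 500, 100, 2, False),
)


def simulate_platform_callsets(
    truth: SyntheticTruth,
    profiles=DEFAULT_PROFILES,
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """Corrupt the child truth into per-platform callsets.

    Each truth SV is detected independently per platform with
    ``profile.sensitivity(type, size)``; detected calls get jittered
    breakpoints, perturbed lengths (floored at 50 bp), and allele
    sequences only when the platform emits them. Spurious calls are added
    at ``fp_rate`` per Mb. Detected calls keep the truth SV id, so the
    planted support pattern in the returned bookkeeping frame (truth id x
    platform label) can be compared against the merged callset directly.
    """
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("platform labels must be unique")
    length = truth.length
    detected: dict = {rec.id: {} for rec in truth.truth}
    callsets = []
    for idx, prof in enumerate(profiles):
        rng = np.random.default_rng([seed, idx])
        records = []
        # detection uniforms drawn up front: lowering a sensitivity can only
        # shrink the detected set under a fixed seed
        detect_u = rng.random(len(truth.truth))
        for i_rec, rec in enumerate(truth.truth):
            hit = detect_u[i_rec] < prof.sensitivity(rec.svtype, rec.svlen)
            detected[rec.id][prof.label] = bool(hit)
            if not hit:
                continue
            start = max(0, rec.start + int(round(rng.normal(0, prof.jitter_sd))))
            svlen = max(50, rec.svlen + int(round(rng.normal(0, prof.len_sd))))
            seq = ""
            if prof.emits_sequence:
                base = rec.alt_seq if rec.svtype == "INS" else rec.ref_seq
                seq = _resize(rng, base, svlen) if base else ""
            records.append(
                SVRecord(
                    id=rec.id,
                    chrom=rec.chrom,
                    start=start,
                    svtype=rec.svtype,
                    svlen=svlen,
                    alt_seq=seq if rec.svtype == "INS" else "",
                    ref_seq=seq if rec.svtype == "DEL" else "",
                    support={prof.label},
                    genotype=rec.genotype,
                )
            )
        n_fp = int(rng.poisson(prof.fp_rate * length / 1e6))
        sizes = DEFAULT_SPECTRUM.sample_sizes(rng, n_fp) if n_fp else []
        for j in range(n_fp):
            svtype = "INS" if rng.random() < 0.5 else "DEL"
            size = int(sizes[j])
            start = int(rng.integers(0, max(1, length - size)))
            records.append(
                SVRecord(
                    id=f"{prof.label}_fp{j:04d}",
                    chrom=truth.chrom,
                    start=start,
                    svtype=svtype,
                    svlen=size,
                    support={prof.label},
                )
            )
        callsets.append(Callset(prof.label, records, {"profile": prof}).sort())
    bookkeeping = pd.DataFrame.from_dict(detected, orient="index").reindex(
        columns=labels
    )
    bookkeeping.index.name = "sv_id"
    return callsets, bookkeeping


# ---------------------------------------------------------------------------
# Paired benchmarks with planted sharing

def simulate_benchmark_pair(
    n_shared_overlap: int,
    n_unique_a: int,
    n_unique_b: int,
    overlap_bp: int,
    a_only_bp: int = 0,
    b_only_bp: int = 0,
    n_a_outside: int = 0,
    n_b_outside: int = 0,
    n_shared_edge: int = 0,
    spacing: int = 5_000,
    sv_len: int = 300,
) -> tuple[BenchmarkSet, BenchmarkSet]:
    """Two benchmark sets with an exactly planted shared/unique structure.

    Region geometry on one chromosome: an A-only zone, the A/B overlap
    zone, then a B-only zone. Shared SVs sit at identical positions in the
    overlap; unique SVs occupy their own grid slots far (``spacing`` bp)
    from any SV of the other side; outside SVs pad each side's totals.
    ``n_shared_edge`` plants matched pairs straddling abutting-but-disjoint
    region boundaries on a separate chromosome — shared calls that lie in
    no common region, as fragmented real region sets produce.
    """
    need = (n_shared_overlap + n_unique_a + n_unique_b) * spacing
    if overlap_bp < need + spacing:
        raise ValueError("overlap_bp too small for the requested SV counts")
    if (n_a_outside and a_only_bp < (n_a_outside + 1) * spacing) or (
        n_b_outside and b_only_bp < (n_b_outside + 1) * spacing
    ):
        raise ValueError("outside zones too small for the requested SV counts")

    chrom, edge_chrom = "chr1", "chrE"
    ov_lo = a_only_bp

    def mk(idx: int, prefix: str, pos: int) -> SVRecord:
        return SVRecord(
            id=f"{prefix}{idx:05d}",
            chrom=chrom,
            start=pos,
            svtype="INS",
            svlen=sv_len,
            hap_support={"paternal"},
        )

    a_svs, b_svs = [], []
    slot = 0
    for i in range(n_shared_overlap):
        pos = ov_lo + (slot + 1) * spacing
        slot += 1
        a_svs.append(mk(i, "sh_a", pos))
        b_svs.append(mk(i, "sh_b", pos))
    for i in range(n_unique_a):
        pos = ov_lo + (slot + 1) * spacing
        slot += 1
        a_svs.append(mk(i, "ua", pos))
    for i in range(n_unique_b):
        pos = ov_lo + (slot + 1) * spacing
        slot += 1
        b_svs.append(mk(i, "ub", pos))
    for i in range(n_a_outside):
        a_svs.append(mk(i, "oa", (i + 1) * spacing))
    for i in range(n_b_outside):
        b_svs.append(mk(i, "ob", a_only_bp + overlap_bp + (i + 1) * spacing))

    a_chcrs = [CHCR(chrom, 0, a_only_bp + overlap_bp, set(), {"paternal"})]
    b_chcrs = [
        CHCR(chrom, ov_lo, a_only_bp + overlap_bp + b_only_bp, set(), {"paternal"})
    ]
    # edge pairs: A region [x, x+2000) and B region [x+2300, x+4300) abut but
    # never overlap; the two partner SVs sit 500 bp apart across the gap
    for i in range(n_shared_edge):
        x = i * 10 * spacing
        a_chcrs.append(CHCR(edge_chrom, x, x + 2000, set(), {"paternal"}))
        b_chcrs.append(CHCR(edge_chrom, x + 2300, x + 4300, set(), {"paternal"}))
        a_svs.append(
            SVRecord(f"ea{i:03d}", edge_chrom, x + 1900, "INS", sv_len, hap_support={"paternal"})
        )
        b_svs.append(
            SVRecord(f"eb{i:03d}", edge_chrom, x + 2400, "INS", sv_len, hap_support={"paternal"})
        )

    def assemble(chcrs, svs, label) -> BenchmarkSet:
        cs = Callset(label, [r.copy() for r in svs]).sort()
        for c in chcrs:
            c.sv_ids = set()
        for rec in cs:
            for c in chcrs:
                if c.contains(rec):
                    c.sv_ids.add(rec.id)
                    break
        bs = BenchmarkSet(list(chcrs), cs)
        bs.validate()
        return bs

    return assemble(a_chcrs, a_svs, "bench_a"), assemble(b_chcrs, b_svs, "bench_b")


# ---------------------------------------------------------------------------
# Long reads

@dataclass
class SimRead:
    id: str
    seq: str
    origin: str  # haplotype label the read was sampled from
    start: int


def simulate_reads(
    haplotypes: dict,
    depth: float,
    mean_len: int = 10_000,
    sd_len: int = 1_500,
    error_rate: float = 0.01,
    seed: int = 0,
) -> list:
    """Uniformly sampled reads with substitution errors, origin-labelled.

    ``haplotypes`` maps an origin label (e.g. 'paternal') to its sequence.
    Total sampled bases approximate ``depth`` times the mean haplotype
    length, split equally across haplotypes. Substitution-only errors; the
    indel-free model keeps k-mer membership the only corruption channel.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    mean_hap = sum(len(s) for s in haplotypes.values()) / len(haplotypes)
    reads = []
    for origin in sorted(haplotypes):
        seq = haplotypes[origin]
        codes = _encode(seq)
        L = len(codes)
        n_reads = max(1, int(round(depth * mean_hap / len(haplotypes) / mean_len)))
        lengths = np.clip(
            np.rint(rng.normal(mean_len, sd_len, size=n_reads)).astype(np.int64), 200, L
        )
        for i in range(n_reads):
            rl = int(lengths[i])
            start = int(rng.integers(0, L - rl + 1))
            sub = codes[start : start + rl].copy()
            n_err = rng.binomial(rl, error_rate)
            if n_err:
                pos = np.unique(rng.integers(0, rl, size=n_err))
                sub[pos] = (sub[pos] + rng.integers(1, 4, size=len(pos)).astype(np.uint8)) % 4
            reads.append(SimRead(f"{origin}_{i:06d}", _decode(sub), origin, start))
    return reads
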