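"""Pairwise SV match predicates and multi-callset clustering/merging.

The merge criteria follow the published integration recipe: calls of the
same type within 1 kb whose sequences differ by less than 20% collapse into
one SV, with a 50% size-ratio and (for deletions) 50% reciprocal-overlap
requirement in the SVmerge style (-d 1000 -l 0.5 -r 0.5). An insertion has
no genomic span, so insertion pairs are compared by breakpoint distance,
size ratio and — when both alleles are available — sequence divergence.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import edlib

from .model import PLATFORMS, Callset, SVRecord

_NUC = re.compile(r"^[ACGTNacgtn]*$")


@dataclass(frozen=True)
class MatchParams:
    """Thresholds deciding whether two SV calls describe the same event.

    max_dist           breakpoint (start) distance cap, bp
    min_size_ratio     min(svlen)/max(svlen) floor, in (0, 1]
    min_recip_overlap  reciprocal-overlap floor for deletion pairs, [0, 1]
    max_divergence     edit-distance fraction cap for insertion alleles
    require_same_type  DEL only matches DEL, INS only INS
    """

    max_dist: int = 1000
    min_size_ratio: float = 0.5
    min_recip_overlap: float = 0.5
    max_divergence: float = 0.2
    require_same_type: bool = True

    def __post_init__(self):
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if not 0 < self.min_size_ratio <= 1:
            raise ValueError("min_size_ratio must be in (0, 1]")
        for name in ("min_recip_overlap", "max_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


#: The published multi-platform merge criteria (1 kb / 0.5 / 0.5 / 20%).
SVMERGE_DEFAULT = MatchParams()

#: Truvari-style evaluation defaults (refdist 500, size ratio 0.7,
#: no reciprocal-overlap requirement, sequence similarity 70%).
TRUVARI_DEFAULT = MatchParams(
    max_dist=500, min_size_ratio=0.7, min_recip_overlap=0.0, max_divergence=0.3
)

PRESETS = {"svmerge-default": SVMERGE_DEFAULT, "truvari-default": TRUVARI_DEFAULT}


def sequence_divergence(a: str, b: str) -> float:
    """Edit distance between two alleles over the longer length.

    0.0 for identical (or two empty) strings, 1.0 for a full-length
    difference; symmetric in its arguments.
    """
    for s in (a, b):
        if not _NUC.match(s):
            raise ValueError(f"non-nucleotide characters in {s[:20]!r}...")
    if not a and not b:
        return 0.0
    if not a or not b:
        return 1.0
    dist = edlib.align(a.upper(), b.upper(), task="distance")["editDistance"]
    return dist / max(len(a), len(b))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for half-open intervals; 0 if either is empty."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def match_pair(a: SVRecord, b: SVRecord, p: MatchParams) -> bool:
    """True iff records a and b describe the same SV under params p.

    All enabled criteria must pass (AND combination): same chromosome,
    same type (when required), start distance, size ratio, and then for
    deletions reciprocal overlap, for insertions sequence divergence when
    both alleles carry sequence. Symmetric in (a, b).
    """
    if a.chrom != b.chrom:
        return False
    if p.require_same_type and a.svtype != b.svtype:
        return False
    if abs(a.start - b.start) > p.max_dist:
        return False
    if min(a.svlen, b.svlen) / max(a.svlen, b.svlen) < p.min_size_ratio:
        return False
    if a.svtype == "DEL" and b.svtype == "DEL":
        if reciprocal_overlap((a.start, a.end), (b.start, b.end)) < p.min_recip_overlap:
            return False
    elif a.svtype == "INS" and b.svtype == "INS":
        if a.alt_seq and b.alt_seq:
            if sequence_divergence(a.alt_seq, b.alt_seq) > p.max_divergence:
                return False
    return True


@dataclass
class Cluster:
    """A group of mutually matching records with a running representative."""

    members: list = field(default_factory=list)
    rep: SVRecord | None = None
    rep_key: tuple | None = None


def _priority_key(rec: SVRecord, priority: dict) -> tuple:
    """Representative ranking: best platform, then smallest start, longest svlen."""
    prio = min((priority.get(lbl, len(priority)) for lbl in rec.support), default=len(priority))
    return (prio, rec.start, -rec.svlen, rec.id)


def cluster_records(records, p: MatchParams, priority: dict, window: int | None = None):
    """Greedy seeded sweep over (chrom, start)-sorted records.

    Each record joins the first existing cluster (creation order) whose
    current representative it matches, else seeds a new cluster. The
    representative of a cluster is its highest-priority member (ties:
    smallest start, then longest svlen). ``window`` prunes clusters whose
    representative start lies more than max_dist behind the sweep; pass
    None to disable pruning (the brute-force configuration).
    """
    ordered = sorted(
        records, key=lambda r: (r.chrom, r.start, _priority_key(r, priority)[0], -r.svlen, r.id)
    )
    clusters: list[Cluster] = []
    active: dict[str, list[Cluster]] = {}
    for rec in ordered:
        pool = active.setdefault(rec.chrom, []) if window is not None else clusters
        if window is not None:
            # retire clusters that can no longer match anything downstream
            while pool and pool[0].rep.start < rec.start - window:
                pool.pop(0)
        home = None
        for cl in pool:
            if cl.rep.chrom == rec.chrom and match_pair(cl.rep, rec, p):
                home = cl
                break
        if home is None:
            home = Cluster()
            clusters.append(home)
            if window is not None:
                pool.append(home)
        home.members.append(rec)
        key = _priority_key(rec, priority)
        if home.rep is None or key < home.rep_key:
            home.rep, home.rep_key = rec, key
    return clusters


def _vote_genotype(members) -> str:
    votes = [m.genotype for m in members if m.genotype != "unknown"]
    het, hom = votes.count("het"), votes.count("hom")
    if het > hom:
        return "het"
    if hom > het:
        return "hom"
    return "unknown"


def cluster_merge(
    callsets,
    p: MatchParams = SVMERGE_DEFAULT,
    priority=PLATFORMS,
    label: str = "merged",
) -> Callset:
    """Merge callsets into cluster representatives with unioned support.

    Every input record belongs to exactly one cluster; the output carries
    one representative per cluster whose support set is the union of the
    member platform labels. Records without a support set inherit their
    callset's label. Cluster sizes are recorded in ``meta['cluster_sizes']``
    keyed by representative id.
    """
    prio_index = {lbl: i for i, lbl in enumerate(priority)}
    pool = []
    for cs in callsets:
        for rec in cs:
            r = rec.copy()
            if not r.support:
                r.support = {cs.label}
            pool.append(r)
    clusters = cluster_records(pool, p, prio_index, window=p.max_dist)
    out = []
    sizes = {}
    for cl in clusters:
        rep = cl.rep.copy()
        rep.support = set().union(*(m.support for m in cl.members))
        rep.hap_support = set().union(*(m.hap_support for m in cl.members))
        rep.genotype = _vote_genotype(cl.members)
        out.append(rep)
        sizes[rep.id] = len(cl.members)
    merged = Callset(label, out, {"cluster_sizes": sizes, "n_input": len(pool)})
    return merged.sort()


def find_match(rec: SVRecord, index: dict, p: MatchParams) -> SVRecord | None:
    """First match for rec in a ``Callset.starts_by_chrom()`` index, or None."""
    entry = index.get(rec.chrom)
    if not entry:
        return None
    starts, recs = entry
    lo = bisect_left(starts, rec.start - p.max_dist)
    hi = bisect_right(starts, rec.start + p.max_dist)
    for cand in recs[lo:hi]:
        if match_pair(rec, cand, p):
            return cand
    return None
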