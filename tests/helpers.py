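"""Independent oracles: brute-force re-implementations used only by tests.

Each oracle restates the rule it checks from scratch (dynamic programming,
exhaustive scans, per-base arrays) without touching the package's own
implementation paths.
"""

from __future__ import annotations

import numpy as np

from svbench.model import SVRecord


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook O(nm) Levenshtein dynamic programme."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def covered_bp_per_base(intervals, chrom_lengths) -> int:
    """Union size by marking a boolean array per chromosome."""
    total = 0
    for chrom, length in chrom_lengths.items():
        mask = np.zeros(length, dtype=bool)
        for c, s, e in intervals:
            if c == chrom:
                mask[s:e] = True
        total += int(mask.sum())
    return total


def match_oracle(a: SVRecord, b: SVRecord, p) -> bool:
    """Plain restatement of the pairwise match criteria."""
    if a.chrom != b.chrom:
        return False
    if p.require_same_type and a.svtype != b.svtype:
        return False
    if abs(a.start - b.start) > p.max_dist:
        return False
    lo, hi = sorted((a.svlen, b.svlen))
    if lo / hi < p.min_size_ratio:
        return False
    if a.svtype == "DEL" and b.svtype == "DEL":
        ov = min(a.start + a.svlen, b.start + b.svlen) - max(a.start, b.start)
        ro = 0.0 if ov <= 0 else min(ov / a.svlen, ov / b.svlen)
        if ro < p.min_recip_overlap:
            return False
    if a.svtype == "INS" and b.svtype == "INS" and a.alt_seq and b.alt_seq:
        div = edit_distance_dp(a.alt_seq, b.alt_seq) / max(len(a.alt_seq), len(b.alt_seq))
        if div > p.max_divergence:
            return False
    return True


def brute_force_clusters(records, p, priority) -> list:
    """All-pairs replay of the greedy seeded sweep, no interval indexing.

    Scans *every* existing cluster for each record and recomputes the
    representative from the member list each time.
    """
    prio = {lbl: i for i, lbl in enumerate(priority)}

    def prio_key(r):
        best = min((prio.get(l, len(prio)) for l in r.support), default=len(prio))
        return (best, r.start, -r.svlen, r.id)

    ordered = sorted(records, key=lambda r: (r.chrom, r.start, prio_key(r)[0], -r.svlen, r.id))
    clusters: list[list] = []
    for rec in ordered:
        placed = False
        for members in clusters:
            rep = min(members, key=prio_key)
            if rep.chrom == rec.chrom and match_oracle(rep, rec, p):
                members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])
    return [frozenset(m.id for m in members) for members in clusters]


def brute_force_classify(truth, test_in_region, p) -> tuple[set, set]:
    """All-pairs greedy matcher: returns (matched truth ids, matched test ids)."""
    pairs = []
    for b in truth:
        for t in test_in_region:
            if match_oracle(b, t, p):
                pairs.append((abs(b.start - t.start), -t.svlen, b.id, t.id))
    pairs.sort()
    used_truth: set = set()
    used_test: set = set()
    for _, _, bid, tid in pairs:
        if bid in used_truth or tid in used_test:
            continue
        used_truth.add(bid)
        used_test.add(tid)
    return used_truth, used_test


def vote_oracle(labels, min_agreeing=2, all_ks=False) -> str:
    """Hand-written restatement of the two integration criteria."""
    winners = []
    decided = [x for x in labels if x in ("paternal", "maternal")]
    for parent in ("paternal", "maternal"):
        n = sum(1 for x in labels if x == parent)
        crit1 = n >= min_agreeing
        denominator = len(labels) if all_ks else len(decided)
        crit2 = n > denominator / 2
        if crit1 and crit2:
            winners.append(parent)
    return winners[0] if len(winners) == 1 else "unassigned"


def retention_oracle(support, svlen) -> bool:
    """Exhaustive restatement of the two retention tiers (default policy)."""
    if svlen < 50:
        return False
    tier1 = "CCS" in support and ("CLR" in support or "ONT" in support)
    tier2 = svlen > 1500 and "ASM" in support and "BN" in support
    return tier1 or tier2


def random_records(rng, n, chroms=("chr1", "chr2"), span=1_000_000, with_seq=False):
    """Random DEL/INS records for fuzzing the clustering/matching paths."""
    from svbench.model import PLATFORMS

    bases = "ACGT"
    out = []
    for i in range(n):
        svtype = "DEL" if rng.random() < 0.5 else "INS"
        svlen = int(rng.integers(50, 5000))
        rec = SVRecord(
            id=f"r{i:04d}",
            chrom=str(rng.choice(chroms)),
            start=int(rng.integers(0, span)),
            svtype=svtype,
            svlen=svlen,
            support={str(rng.choice(PLATFORMS))},
        )
        if with_seq and svtype == "INS" and svlen <= 300:
            rec.alt_seq = "".join(rng.choice(list(bases), size=svlen))
        out.append(rec)
    return out
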