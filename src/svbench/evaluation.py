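"""Scoring callsets against the benchmark inside CHCRs.

Truvari-style evaluation: test calls outside every CHCR are ignored; inside,
each benchmark SV may consume at most one test call (greedy, nearest
breakpoint first), giving TP/FP/FN and precision/recall/F1. Also here:
F1-versus-depth curves, SURVIVOR-style replicate-consensus merging of NGS
callsets, and the region-aware comparison of two benchmarks.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .chcr import BenchmarkSet
from .matching import MatchParams, SVMERGE_DEFAULT, TRUVARI_DEFAULT, match_pair
from .model import Callset, SVRecord


@dataclass
class EvalResult:
    """TP/FP/FN counts with the derived precision/recall/F1."""

    tp: int
    fp: int
    fn: int
    stratum: str | None = None
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        pr = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / pr if pr else 0.0


def compute_prf(tp: int, fp: int, fn: int, stratum: str | None = None) -> EvalResult:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    return EvalResult(tp, fp, fn, stratum)


def _candidate_pairs(truth: list, test: list, p: MatchParams):
    """(distance, i, j) for every matching truth/test pair, via a start window."""
    by_chrom: dict = {}
    for j, t in enumerate(test):
        by_chrom.setdefault(t.chrom, []).append(j)
    for js in by_chrom.values():
        js.sort(key=lambda j: test[j].start)
    pairs = []
    for i, b in enumerate(truth):
        js = by_chrom.get(b.chrom, [])
        starts = [test[j].start for j in js]
        lo = bisect_left(starts, b.start - p.max_dist)
        hi = bisect_right(starts, b.start + p.max_dist)
        for j in js[lo:hi]:
            if match_pair(b, test[j], p):
                pairs.append((abs(b.start - test[j].start), i, j))
    return pairs


def classify_calls(
    test: Callset, bench: BenchmarkSet, p: MatchParams = TRUVARI_DEFAULT
) -> tuple[list, list, list]:
    """Greedy one-to-one matching of in-CHCR test calls to benchmark SVs.

    Returns (tp_pairs, fp_records, fn_records): tp_pairs are (benchmark SV,
    test record) pairs; fp_records are in-CHCR test records that matched
    nothing; fn_records are unmatched benchmark SVs. Ties on breakpoint
    distance prefer the longer test call.
    """
    regions = bench.regions()
    in_region = [r for r in test if regions.contains(r.chrom, *r.span())]
    truth = sorted(bench.svs.records, key=SVRecord.sort_key)
    # ties: longer test SV wins, then deterministic id order
    pairs = sorted(
        _candidate_pairs(truth, in_region, p),
        key=lambda d_i_j: (
            d_i_j[0],
            -in_region[d_i_j[2]].svlen,
            truth[d_i_j[1]].id,
            in_region[d_i_j[2]].id,
        ),
    )
    matched_truth: set = set()
    matched_test: set = set()
    tp_pairs = []
    for dist, i, j in pairs:
        if i in matched_truth or j in matched_test:
            continue
        matched_truth.add(i)
        matched_test.add(j)
        tp_pairs.append((truth[i], in_region[j]))
    fn = [b for i, b in enumerate(truth) if i not in matched_truth]
    fp = [t for j, t in enumerate(in_region) if j not in matched_test]
    return tp_pairs, fp, fn


def evaluate(
    test: Callset, bench: BenchmarkSet, p: MatchParams = TRUVARI_DEFAULT, stratum=None
) -> EvalResult:
    tp_pairs, fp, fn = classify_calls(test, bench, p)
    return compute_prf(len(tp_pairs), len(fp), len(fn), stratum)


def depth_curve(
    callsets_by_depth: dict,
    bench: BenchmarkSet,
    p: MatchParams = TRUVARI_DEFAULT,
    tsv_path: str | None = None,
    plot_path: str | None = None,
) -> list:
    """One EvalResult per sequencing depth, sorted by depth."""
    if len(callsets_by_depth) < 1:
        raise ValueError("at least one depth required")
    curve = []
    for depth in sorted(callsets_by_depth):
        res = evaluate(callsets_by_depth[depth], bench, p, stratum=f"depth={depth}")
        curve.append((depth, res))
    if tsv_path is not None:
        pd.DataFrame(
            [
                {
                    "depth": d,
                    "tp": r.tp,
                    "fp": r.fp,
                    "fn": r.fn,
                    "precision": r.precision,
                    "recall": r.recall,
                    "f1": r.f1,
                }
                for d, r in curve
            ]
        ).to_csv(tsv_path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot([d for d, _ in curve], [r.f1 for _, r in curve], marker="o")
        ax.set_xlabel("sequencing depth (x)")
        ax.set_ylabel("F1-score")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return curve


def merge_replicates(
    replicates,
    max_dist: int = 1000,
    min_support: int = 2,
    same_type: bool = True,
    same_strand: bool = False,
    min_size: int = 30,
) -> Callset:
    """SURVIVOR-style consensus over replicate callsets (params "1000 2 1 1 0 30").

    Calls across replicates cluster when within ``max_dist`` bp (and of the
    same type when ``same_type``); clusters supported by at least
    ``min_support`` distinct replicates whose representative is at least
    ``min_size`` bp are kept. ``same_strand`` is parsed for fidelity to the
    parameter string but is inert for the symmetric DEL/INS types.
    """
    del same_strand  # strand has no meaning for DEL/INS
    if len(replicates) < 1:
        raise ValueError("at least one replicate required")
    tagged = []
    for rep in replicates:
        for rec in rep:
            r = rec.copy()
            r.support = {rep.label}
            tagged.append((rep.label, r))
    tagged.sort(key=lambda lr: lr[1].sort_key())

    clusters: list[list] = []
    active: dict = {}
    for label, rec in tagged:
        pool = active.setdefault(rec.chrom, [])
        while pool and pool[0][0].start < rec.start - max_dist:
            pool.pop(0)
        home = None
        for entry in pool:
            seed = entry[0]
            if abs(seed.start - rec.start) <= max_dist and (
                not same_type or seed.svtype == rec.svtype
            ):
                home = entry
                break
        if home is None:
            home = [rec]
            pool.append(home)
            clusters.append(home)
        else:
            home.append(rec)

    out = []
    for members in clusters:
        labels = set().union(*(m.support for m in members))
        if len(labels) < min_support:
            continue
        rep = min(members, key=lambda m: (m.start, -m.svlen, m.id)).copy()
        if rep.svlen < min_size:
            continue
        rep.support = labels
        out.append(rep)
    return Callset("consensus", out).sort()


@dataclass
class BenchmarkComparison:
    """Shared/unique accounting between two benchmark sets."""

    total_a: int
    total_b: int
    shared_total: int
    overlap_bp: int
    in_overlap_a: int
    in_overlap_b: int
    shared_overlap: int
    unique_a: int = field(init=False)
    unique_b: int = field(init=False)
    shared_frac_a: float = field(init=False)
    shared_frac_b: float = field(init=False)

    def __post_init__(self):
        self.unique_a = self.in_overlap_a - self.shared_overlap
        self.unique_b = self.in_overlap_b - self.shared_overlap
        self.shared_frac_a = (
            self.shared_overlap / self.in_overlap_a if self.in_overlap_a else 0.0
        )
        self.shared_frac_b = (
            self.shared_overlap / self.in_overlap_b if self.in_overlap_b else 0.0
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _count_matched_pairs(recs_a: list, recs_b: list, p: MatchParams) -> int:
    """Greedy one-to-one pair count with side-symmetric tie-breaking."""
    pairs = _candidate_pairs(recs_a, recs_b, p)
    pairs.sort(
        key=lambda dij: (
            dij[0],
            min(recs_a[dij[1]].start, recs_b[dij[2]].start),
            max(recs_a[dij[1]].start, recs_b[dij[2]].start),
            min(recs_a[dij[1]].svlen, recs_b[dij[2]].svlen),
        )
    )
    used_a: set = set()
    used_b: set = set()
    n = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n += 1
    return n


def compare_benchmarks(
    a: BenchmarkSet, b: BenchmarkSet, p: MatchParams = SVMERGE_DEFAULT
) -> BenchmarkComparison:
    """Shared SVs overall, the overlap of the two region sets, and the
    shared/unique split restricted to that overlap."""
    shared_total = _count_matched_pairs(list(a.svs), list(b.svs), p)
    overlap = a.regions().intersection(b.regions())
    in_a = [r for r in a.svs if overlap.contains(r.chrom, *r.span())]
    in_b = [r for r in b.svs if overlap.contains(r.chrom, *r.span())]
    shared_overlap = _count_matched_pairs(in_a, in_b, p)
    return BenchmarkComparison(
        total_a=len(a.svs),
        total_b=len(b.svs),
        shared_total=shared_total,
        overlap_bp=overlap.total_bp(),
        in_overlap_a=len(in_a),
        in_overlap_b=len(in_b),
        shared_overlap=shared_overlap,
    )
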