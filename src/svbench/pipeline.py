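"""End-to-end synthetic pipeline runs: simulate -> merge -> integrate ->
annotate -> CHCR -> evaluate, with the generator's bookkeeping carried
through so recovery can be scored against the planted truth."""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chcr import BenchmarkSet, annotate_hap_support, build_chcrs
from .integration import RetentionPolicy, build_high_confidence
from .matching import SVMERGE_DEFAULT, MatchParams
from .model import Callset, SVRecord
from .simulate import (
    PlatformProfile,
    SyntheticTruth,
    simulate_platform_callsets,
    simulate_reference,
    simulate_trio,
)

#: Platform sensitivity triple used by the standard study-condition fixture:
#: CCS 0.9, CLR 0.8, ONT 0.7, with assembly and optical mapping behind them.
FIXTURE_PROFILES = (
    PlatformProfile("CCS", 0.90, 0.90, (("INS", 5000, float("inf"), 0.20),), 5, 2, 5, True),
    PlatformProfile("CLR", 0.80, 0.80, (("INS", 5000, float("inf"), 0.25),), 20, 10, 8, True),
    PlatformProfile("ONT", 0.70, 0.70, (), 30, 15, 8, True),
    PlatformProfile("ASM", 0.85, 0.85, (), 2, 1, 3, True),
    PlatformProfile("BN", 0.80, 0.80, (("*", 0, 1000, 0.0),), 500, 100, 2, False),
)


@dataclass
class PipelineRun:
    truth: SyntheticTruth
    callsets: list
    bookkeeping: pd.DataFrame
    highconf: Callset
    audit: object
    annotated: Callset
    benchmark: BenchmarkSet

    def expected_retained_ids(self, policy: RetentionPolicy = RetentionPolicy()) -> set:
        """Truth SVs whose *planted* detection pattern satisfies the tiers."""
        by_id = {r.id: r for r in self.truth.truth}
        out = set()
        for sv_id, row in self.bookkeeping.iterrows():
            support = {lbl for lbl, hit in row.items() if hit}
            if policy.retains(support, by_id[sv_id].svlen):
                out.add(sv_id)
        return out

    def recovery(self, policy: RetentionPolicy = RetentionPolicy()) -> tuple[float, float]:
        """(recall, precision) of the high-confidence callset vs the planted
        expectation. Detected calls keep their truth id, so id membership is
        the matching criterion."""
        expected = self.expected_retained_ids(policy)
        got = {r.id for r in self.highconf}
        if not expected:
            return 0.0, 0.0
        recall = len(expected & got) / len(expected)
        precision = len(expected & got) / len(got) if got else 0.0
        return recall, precision


def run_trio_pipeline(
    seed: int,
    length: int = 2_000_000,
    sv_count: int = 300,
    profiles=FIXTURE_PROFILES,
    match_params: MatchParams = SVMERGE_DEFAULT,
    policy: RetentionPolicy = RetentionPolicy(),
) -> PipelineRun:
    """Run the full benchmark-construction pipeline on a seeded fixture."""
    ref, elements = simulate_reference(length, seed=seed)
    truth = simulate_trio(ref, sv_count, seed=seed + 1, elements=elements)
    callsets, bookkeeping = simulate_platform_callsets(truth, profiles, seed=seed + 2)
    highconf, audit = build_high_confidence(
        callsets, excl=None, match_params=match_params, policy=policy
    )
    pat_calls, mat_calls = truth.assembly_callsets()
    annotated = annotate_hap_support(highconf, pat_calls, mat_calls, match_params)
    pat_cov, mat_cov = truth.coverage_regions()
    benchmark = build_chcrs(annotated, pat_cov, mat_cov)
    return PipelineRun(truth, callsets, bookkeeping, highconf, audit, annotated, benchmark)


def corrupted_test_callset(
    benchmark: BenchmarkSet,
    sensitivity: float = 0.9,
    fp_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[Callset, float, float]:
    """A test callset with planted dropouts and in-CHCR spurious calls.

    Each benchmark SV is kept with probability ``sensitivity``;
    ``fp_fraction`` of the benchmark count is added as spurious calls
    placed inside CHCRs well away (>2 kb) from any benchmark SV. Returns
    (callset, planted_recall, planted_precision) where the planted values
    are the exact rates realised by the random draws.
    """
    rng = np.random.default_rng(seed)
    kept = [r.copy() for r in benchmark.svs if rng.random() < sensitivity]
    n_fp = int(round(fp_fraction * len(benchmark.svs)))
    sv_positions = sorted((r.chrom, r.start) for r in benchmark.svs)
    fps = []
    grid = []
    for c in benchmark.chcrs:
        pos = c.start + 1000
        while pos < c.end - 1000:
            grid.append((c.chrom, pos))
            pos += 5000
    for t in rng.permutation(len(grid)):
        chrom, pos = grid[int(t)]
        if len(fps) >= n_fp:
            break
        i = bisect_left(sv_positions, (chrom, pos))
        near = []
        if i > 0:
            near.append(sv_positions[i - 1])
        if i < len(sv_positions):
            near.append(sv_positions[i])
        if any(c == chrom and abs(p - pos) < 2000 for c, p in near):
            continue
        fps.append(
            SVRecord(
                id=f"spurious{len(fps):04d}",
                chrom=chrom,
                start=pos,
                svtype="INS" if rng.random() < 0.5 else "DEL",
                svlen=int(rng.integers(60, 400)),
            )
        )
    records = [r for r in kept] + fps
    planted_recall = len(kept) / len(benchmark.svs) if len(benchmark.svs) else 0.0
    planted_precision = len(kept) / (len(kept) + len(fps)) if kept or fps else 0.0
    return Callset("test", records).sort(), planted_recall, planted_precision


def depth_titration_callsets(
    benchmark: BenchmarkSet,
    depths=(2, 5, 8, 11, 20),
    d0: float = 4.0,
    seed: int = 0,
) -> dict:
    """Per-depth callsets under a saturating sensitivity model s(d) = 1 - exp(-d/d0)."""
    out = {}
    for depth in depths:
        rng = np.random.default_rng([seed, int(depth * 100)])
        s = 1.0 - float(np.exp(-depth / d0))
        recs = [r.copy() for r in benchmark.svs if rng.random() < s]
        out[depth] = Callset(f"depth{depth}", recs).sort()
    return out
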