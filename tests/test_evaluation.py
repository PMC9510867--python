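"""Benchmark evaluation: classification, P/R/F1, depth curves, consensus,
benchmark comparison."""

import pytest

from helpers import brute_force_classify, random_records
from svbench.chcr import BenchmarkSet, CHCR
from svbench.evaluation import (
    classify_calls,
    compare_benchmarks,
    compute_prf,
    depth_curve,
    evaluate,
    merge_replicates,
)
from svbench.matching import TRUVARI_DEFAULT
from svbench.model import Callset, SVRecord


def _rec(rid, start, svtype="INS", svlen=300, chrom="chr1", **kw):
    return SVRecord(rid, chrom, start, svtype, svlen, **kw)


def _bench(records, end=1_000_000, chrom="chr1"):
    cs = Callset("benchmark", [r.copy() for r in records]).sort()
    for r in cs:
        r.hap_support = r.hap_support or {"paternal"}
    chcr = CHCR(chrom, 0, end, {r.id for r in cs}, {"paternal"})
    bs = BenchmarkSet([chcr], cs)
    bs.validate()
    return bs


class TestClassifyCalls:
    def test_identical_callsets_score_perfectly(self):
        truth = [_rec(f"b{i}", 10_000 * (i + 1)) for i in range(20)]
        bs = _bench(truth)
        res = evaluate(Callset("t", [r.copy() for r in truth]).sort(), bs)
        assert (res.tp, res.fp, res.fn) == (20, 0, 0)
        assert res.precision == res.recall == res.f1 == 1.0

    def test_empty_test_callset_is_all_false_negatives(self):
        bs = _bench([_rec(f"b{i}", 10_000 * (i + 1)) for i in range(5)])
        res = evaluate(Callset("t"), bs)
        assert (res.tp, res.fp, res.fn) == (0, 0, 5)

    def test_calls_outside_chcrs_are_ignored(self):
        bs = _bench([_rec("b0", 50_000)], end=100_000)
        test = Callset(
            "t", [_rec("t0", 50_000), _rec("t1", 400_000), _rec("t2", 900_000)]
        ).sort()
        res = evaluate(test, bs)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_conservation_tp_plus_fn_is_benchmark_size(self, rng):
        truth = [_rec(f"b{i}", int(p)) for i, p in enumerate(rng.integers(0, 900_000, 200))]
        bs = _bench(truth)
        test = Callset("t", random_records(rng, 300, chroms=("chr1",), span=900_000)).sort()
        tp_pairs, fp, fn = classify_calls(test, bs)
        assert len(tp_pairs) + len(fn) == len(bs.svs)

    def test_matches_bruteforce_matcher(self, rng):
        for trial in range(6):
            truth = [
                _rec(f"b{i}", int(p), "DEL" if rng.random() < 0.5 else "INS",
                     int(rng.integers(50, 900)))
                for i, p in enumerate(rng.integers(0, 500_000, 120))
            ]
            bs = _bench(truth)
            test = Callset(
                "t", random_records(rng, 150, chroms=("chr1",), span=500_000)
            ).sort()
            tp_pairs, fp, fn = classify_calls(test, bs, TRUVARI_DEFAULT)
            regions = bs.regions()
            in_region = [r for r in test if regions.contains(r.chrom, *r.span())]
            want_truth, want_test = brute_force_classify(
                sorted(bs.svs.records, key=lambda r: r.sort_key()), in_region, TRUVARI_DEFAULT
            )
            assert {b.id for b, _ in tp_pairs} == want_truth
            assert {t.id for _, t in tp_pairs} == want_test

    def test_planted_dropout_and_fp_rates_recover(self, rng):
        from svbench.pipeline import corrupted_test_callset

        truth = [_rec(f"b{i}", 5_000 * (i + 1)) for i in range(199)]
        bs = _bench(truth)
        test, planted_r, planted_p = corrupted_test_callset(bs, 0.9, 0.05, seed=77)
        res = evaluate(test, bs)
        assert res.recall == pytest.approx(planted_r, abs=1e-9)
        assert res.precision == pytest.approx(planted_p, abs=1e-9)


class TestComputePrf:
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r,f1",
        [
            (8, 2, 2, 0.8, 0.8, 0.8),
            (0, 0, 10, 0.0, 0.0, 0.0),
            (90, 10, 30, 0.9, 0.75, 0.8181818181818181),
            (0, 0, 0, 0.0, 0.0, 0.0),
        ],
    )
    def test_closed_form(self, tp, fp, fn, p, r, f1):
        res = compute_prf(tp, fp, fn)
        assert (res.precision, res.recall) == pytest.approx((p, r))
        assert res.f1 == pytest.approx(f1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_prf(-1, 0, 0)


class TestDepthCurve:
    def test_same_callset_at_all_depths_is_flat(self):
        truth = [_rec(f"b{i}", 10_000 * (i + 1)) for i in range(10)]
        bs = _bench(truth)
        test = Callset("t", [r.copy() for r in truth]).sort()
        curve = depth_curve({5: test, 11: test, 20: test}, bs)
        assert [d for d, _ in curve] == [5, 11, 20]
        assert len({r.f1 for _, r in curve}) == 1

    def test_f1_rises_with_depth_under_saturating_sensitivity(self):
        from svbench.pipeline import depth_titration_callsets

        truth = [_rec(f"b{i}", 400 + 450 * i) for i in range(2000)]
        bs = _bench(truth, end=1_000_000)
        callsets = depth_titration_callsets(bs, depths=(0.5, 2, 5, 8, 11, 20), seed=5)
        curve = depth_curve(callsets, bs)
        f1s = [r.f1 for _, r in curve]
        assert all(b >= a for a, b in zip(f1s, f1s[1:]))

    def test_empty_callset_scores_zero(self):
        bs = _bench([_rec("b0", 1000)])
        curve = depth_curve({0: Callset("none"), 10: Callset("none")}, bs)
        assert curve[0][1].f1 == 0.0

    def test_writes_tsv_and_plot(self, tmp_path):
        bs = _bench([_rec("b0", 1000)])
        test = Callset("t", [_rec("t0", 1000)])
        depth_curve(
            {1: test, 2: test},
            bs,
            tsv_path=str(tmp_path / "c.tsv"),
            plot_path=str(tmp_path / "c.png"),
        )
        assert (tmp_path / "c.tsv").exists() and (tmp_path / "c.png").exists()


class TestMergeReplicates:
    def _replicates(self):
        shared = [_rec(f"s{i}", 10_000 * (i + 1), svlen=200) for i in range(5)]
        reps = []
        for j in range(3):
            recs = [r.copy() for r in shared]
            recs.append(_rec(f"only{j}", 500_000 + j * 50_000, svlen=200))
            reps.append(Callset(f"rep{j}", recs).sort())
        return reps

    def test_consensus_keeps_recurrent_and_drops_singletons(self):
        merged = merge_replicates(self._replicates())
        ids = {r.id for r in merged}
        assert ids == {f"s{i}" for i in range(5)}

    def test_size_floor_applies_to_representative(self):
        reps = [
            Callset(f"r{j}", [_rec("a", 1000, svlen=40), _rec("b", 50_000, svlen=25)]).sort()
            for j in range(3)
        ]
        merged = merge_replicates(reps, min_size=30)
        assert {r.id for r in merged} == {"a"}

    def test_output_shrinks_as_min_support_rises(self):
        reps = self._replicates()
        sizes = [len(merge_replicates(reps, min_support=m)) for m in (1, 2, 3)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes == [8, 5, 5]


class TestCompareBenchmarks:
    def test_self_comparison_shares_everything(self):
        truth = [_rec(f"b{i}", 10_000 * (i + 1)) for i in range(30)]
        bs = _bench(truth)
        cmp_res = compare_benchmarks(bs, bs)
        assert cmp_res.shared_total == 30
        assert cmp_res.unique_a == cmp_res.unique_b == 0
        assert cmp_res.shared_frac_a == cmp_res.shared_frac_b == 1.0

    def test_disjoint_regions_share_no_overlap(self):
        a = _bench([_rec("a0", 5_000)], end=100_000)
        b_cs = Callset("b", [_rec("b0", 505_000, hap_support={"paternal"})])
        b = BenchmarkSet([CHCR("chr1", 500_000, 600_000, {"b0"}, {"paternal"})], b_cs)
        cmp_res = compare_benchmarks(a, b)
        assert cmp_res.overlap_bp == 0
        assert cmp_res.in_overlap_a == cmp_res.in_overlap_b == 0
        assert cmp_res.shared_overlap == 0

    def test_shared_counts_are_symmetric(self, rng):
        from svbench.simulate import simulate_benchmark_pair

        a, b = simulate_benchmark_pair(
            n_shared_overlap=120, n_unique_a=50, n_unique_b=70, overlap_bp=2_000_000,
            a_only_bp=500_000, b_only_bp=500_000, n_a_outside=30, n_b_outside=20,
        )
        ab = compare_benchmarks(a, b)
        ba = compare_benchmarks(b, a)
        assert ab.shared_total == ba.shared_total
        assert ab.shared_overlap == ba.shared_overlap
        assert (ab.unique_a, ab.unique_b) == (ba.unique_b, ba.unique_a)

    def test_planted_sixty_percent_sharing_recovers(self):
        from svbench.simulate import simulate_benchmark_pair

        a, b = simulate_benchmark_pair(
            n_shared_overlap=600, n_unique_a=400, n_unique_b=400, overlap_bp=9_000_000,
        )
        cmp_res = compare_benchmarks(a, b)
        assert cmp_res.shared_frac_a == pytest.approx(0.60, abs=0.02)
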