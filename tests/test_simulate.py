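"""Determinism and statistical sanity of the synthetic-data generators."""

import numpy as np

from svbench.simulate import (
    DEFAULT_SPECTRUM,
    PlatformProfile,
    simulate_platform_callsets,
    simulate_reads,
    simulate_reference,
    simulate_trio,
)


class TestReference:
    def test_same_seed_reproduces_sequence_and_elements(self):
        a_seq, a_el = simulate_reference(200_000, seed=3)
        b_seq, b_el = simulate_reference(200_000, seed=3)
        assert a_seq == b_seq and a_el == b_el

    def test_zero_density_plants_no_elements(self):
        _, elements = simulate_reference(200_000, element_density=0, seed=3)
        assert elements == []

    def test_element_count_is_poisson_consistent(self):
        lam = 50 * 2.0  # 50 per Mb at 2 Mb
        _, elements = simulate_reference(2_000_000, element_density=50, seed=4)
        assert abs(len(elements) - lam) <= 4 * np.sqrt(lam)


class TestTrio:
    def test_zero_svs_leaves_only_snv_differences(self):
        ref, _ = simulate_reference(100_000, seed=8)
        truth = simulate_trio(ref, 0, seed=9)
        assert len(truth.truth) == 0
        for hap in (truth.father[0], truth.mother[0]):
            assert len(hap) == len(ref)
            mismatches = sum(1 for a, b in zip(hap, ref) if a != b)
            assert 0 < mismatches < 0.01 * len(ref)

    def test_size_histogram_shows_both_element_peaks(self, rng):
        sizes = DEFAULT_SPECTRUM.sample_sizes(np.random.default_rng(10), 5000)
        small = sizes[(sizes >= 100) & (sizes <= 1000)]
        counts, edges = np.histogram(small, bins=np.arange(100, 1025, 25))
        mode_small = edges[np.argmax(counts)] + 12.5
        assert abs(mode_small - 300) <= 30
        large = sizes[(sizes >= 4000) & (sizes <= 8000)]
        counts, edges = np.histogram(large, bins=np.arange(4000, 8250, 250))
        mode_large = edges[np.argmax(counts)] + 125
        assert abs(mode_large - 6000) <= 600

    def test_haplotypes_reconstruct_from_truth_lists(self):
        # independent reconstruction: apply SNVs then SVs by hand
        ref, el = simulate_reference(150_000, seed=12)
        truth = simulate_trio(ref, 25, seed=13, elements=el)
        for parent, hap_idx, emitted in (
            ("father", 0, truth.father[0]),
            ("mother", 1, truth.mother[1]),
        ):
            arr = bytearray(ref.encode())
            for pos, base in truth.snvs[(parent, hap_idx)]:
                arr[pos] = ord(base)
            carried = sorted(
                (sv for sv in truth.all_svs if (parent, hap_idx) in sv.carriers),
                key=lambda s: s.start,
            )
            pieces, cur = [], 0
            for sv in carried:
                pieces.append(bytes(arr[cur : sv.start]))
                if sv.svtype == "DEL":
                    cur = sv.start + sv.svlen
                else:
                    pieces.append(sv.seq.encode())
                    cur = sv.start
            pieces.append(bytes(arr[cur:]))
            assert b"".join(pieces).decode() == emitted

    def test_child_genotypes_reflect_carrier_structure(self):
        ref, el = simulate_reference(200_000, seed=20)
        truth = simulate_trio(ref, 30, seed=21, elements=el)
        for rec in truth.truth:
            assert rec.hap_support
            assert (rec.genotype == "hom") == (len(rec.hap_support) == 2)

    def test_shared_region_is_variant_free(self):
        ref, el = simulate_reference(200_000, seed=22)
        truth = simulate_trio(ref, 30, seed=23, elements=el)
        shared_end = truth.shared_regions.intervals[0][2]
        assert all(sv.start >= shared_end for sv in truth.all_svs)
        prefix = ref[:shared_end]
        for seqs in (truth.father, truth.mother):
            for hap in seqs:
                assert hap[:shared_end] == prefix


class TestPlatformCallsets:
    def test_perfect_profiles_echo_the_truth(self, small_trio):
        profiles = tuple(
            PlatformProfile(lbl, 1.0, 1.0, (), 0, 0, 0.0)
            for lbl in ("CCS", "CLR", "ONT", "ASM", "BN")
        )
        callsets, bookkeeping = simulate_platform_callsets(small_trio, profiles, seed=2)
        for cs in callsets:
            assert len(cs) == len(small_trio.truth)
            for got, want in zip(cs, small_trio.truth):
                assert (got.start, got.svtype, got.svlen) == (
                    want.start, want.svtype, want.svlen
                )
        assert bool(bookkeeping.all().all())

    def test_detection_rate_tracks_sensitivity(self, small_trio):
        profiles = (PlatformProfile("CCS", 0.8, 0.8, (), 0, 0, 0.0),)
        n = len(small_trio.truth)
        hits = []
        for seed in range(25):
            _, bk = simulate_platform_callsets(small_trio, profiles, seed=seed)
            hits.append(int(bk["CCS"].sum()))
        total, trials = sum(hits), 25 * n
        sd = np.sqrt(trials * 0.8 * 0.2)
        assert abs(total - 0.8 * trials) <= 3 * sd

    def test_breakpoint_jitter_matches_half_normal_mean(self, small_trio):
        sd = 120.0
        profiles = (PlatformProfile("X1", 1.0, 1.0, (), jitter_sd=sd, len_sd=0, fp_rate=0.0),)
        offsets = []
        truth_pos = {r.id: r.start for r in small_trio.truth}
        for seed in range(40):
            callsets, _ = simulate_platform_callsets(small_trio, profiles, seed=seed)
            offsets.extend(
                abs(r.start - truth_pos[r.id]) for r in callsets[0] if r.id in truth_pos
            )
        expected = sd * np.sqrt(2 / np.pi)
        assert abs(np.mean(offsets) - expected) <= 0.1 * expected

    def test_sequence_free_platform_emits_no_alleles(self, small_trio):
        callsets, _ = simulate_platform_callsets(small_trio, seed=3)
        bn = next(cs for cs in callsets if cs.label == "BN")
        assert all(not r.alt_seq and not r.ref_seq for r in bn)


class TestReads:
    def test_total_bases_track_requested_depth(self, small_trio):
        haps = {"paternal": small_trio.child_paternal, "maternal": small_trio.child_maternal}
        reads = simulate_reads(haps, depth=30, error_rate=0.0, seed=1)
        total = sum(len(r.seq) for r in reads)
        expected = 30 * np.mean([len(s) for s in haps.values()])
        assert abs(total - expected) <= 0.05 * expected

    def test_error_rate_matches_request(self, small_trio):
        haps = {"paternal": small_trio.child_paternal}
        reads = simulate_reads(haps, depth=2, error_rate=0.01, seed=2)
        mismatches = bases = 0
        hap = small_trio.child_paternal
        for r in reads[:40]:
            source = hap[r.start : r.start + len(r.seq)]
            mismatches += sum(1 for a, b in zip(source, r.seq) if a != b)
            bases += len(r.seq)
        sd = np.sqrt(bases * 0.01 * 0.99)
        # substitutions can collide on a position, shaving the realised rate
        assert abs(mismatches - 0.01 * bases) <= 3 * sd + 0.01 * 0.01 * bases

    def test_same_seed_reproduces_reads(self, small_trio):
        haps = {"paternal": small_trio.child_paternal}
        a = simulate_reads(haps, depth=1, seed=9)
        b = simulate_reads(haps, depth=1, seed=9)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]
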