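"""k-mer index construction, per-k voting, and the cross-k integration rule."""

import itertools

import numpy as np
import pytest

from helpers import vote_oracle
from svbench.triobin import (
    KmerIndex,
    VotingPolicy,
    build_kmer_index,
    canonical_kmer,
    kmer_hashes,
    partition_reads,
    vote_across_k,
    vote_single_k,
)

LABELS = ("paternal", "maternal", "undecided")


def _enumerate_canonical(seq, k):
    return {canonical_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)}


class TestKmerIndex:
    def test_identical_parents_have_no_unique_kmers(self):
        seq = "ACGTACGTACGTACGT"
        idx = build_kmer_index([seq], [seq], 5)
        assert idx.n_paternal == 0 and idx.n_maternal == 0

    def test_small_index_matches_exhaustive_enumeration(self):
        pat, mat = "AAAAACGTT", "AAATACGTT"
        idx = build_kmer_index([pat], [mat], 4)
        pat_kmers = _enumerate_canonical(pat, 4)
        mat_kmers = _enumerate_canonical(mat, 4)
        expect_pat = pat_kmers - mat_kmers
        expect_mat = mat_kmers - pat_kmers
        assert idx.n_paternal == len(expect_pat)
        assert idx.n_maternal == len(expect_mat)
        for kmer in expect_pat:
            assert idx.assign_kmer(kmer) == "paternal"
        for kmer in expect_mat:
            assert idx.assign_kmer(kmer) == "maternal"
        for kmer in pat_kmers & mat_kmers:
            assert idx.assign_kmer(kmer) is None

    def test_snv_scale_unique_sets_match_enumeration(self, rng):
        # parents differing by scattered substitutions; compare the hashed
        # index against exact string enumeration
        k = 21
        base = "".join(rng.choice(list("ACGT"), size=20_000))
        mat = list(base)
        pos = rng.choice(len(base) - 2 * k, size=20, replace=False) + k
        for p in pos:
            mat[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mat[p]]
        mat = "".join(mat)
        idx = build_kmer_index([base], [mat], k)
        expect_pat = _enumerate_canonical(base, k) - _enumerate_canonical(mat, k)
        expect_mat = _enumerate_canonical(mat, k) - _enumerate_canonical(base, k)
        assert idx.n_paternal == len(expect_pat)
        assert idx.n_maternal == len(expect_mat)
        assert all(idx.assign_kmer(m) == "paternal" for m in expect_pat)
        # each SNV creates at most 2k unique k-mers per side
        assert idx.n_paternal <= 2 * k * len(pos)

    def test_k_longer_than_sequence_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_kmer_index(["ACGT"], ["ACGTACGT"], 8)

    def test_canonical_hash_is_strand_invariant(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for k in (5, 21, 81):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            rc = seq.translate(comp)[::-1]
            h_fwd = np.sort(kmer_hashes(seq, k))
            h_rc = np.sort(kmer_hashes(rc, k))
            assert np.array_equal(h_fwd, h_rc)

    def test_non_acgt_windows_are_dropped(self):
        h = kmer_hashes("ACGTNACGT", 4)
        # windows touching the N (positions 1-4) disappear: 2 of 6 remain
        assert len(h) == 2


class TestVoteSingleK:
    def test_majority_labels(self):
        idx = build_kmer_index(["AAAAACGTT"], ["AAATACGTT"], 4)
        label, n_pat, n_mat = vote_single_k("AAAAACGTT", idx)
        assert label == "paternal" and n_pat > 0 and n_mat == 0

    def test_no_markers_is_undecided(self):
        idx = build_kmer_index(["AAAAACGTT"], ["AAATACGTT"], 4)
        label, n_pat, n_mat = vote_single_k("GGGGGGGG", idx)
        assert (label, n_pat, n_mat) == ("undecided", 0, 0)

    def test_noisy_reads_from_one_haplotype_vote_for_it(self, small_trio, rng):
        from svbench.simulate import simulate_reads

        idx = build_kmer_index(list(small_trio.father), list(small_trio.mother), 21)
        reads = simulate_reads(
            {"paternal": small_trio.child_paternal}, depth=2, error_rate=0.01, seed=42
        )
        # reads wholly inside the homozygous-identical region carry no
        # markers by construction and cannot vote
        shared_end = small_trio.shared_regions.intervals[0][2]
        informative = [r for r in reads if r.start + len(r.seq) > shared_end]
        labels = [vote_single_k(r.seq, idx)[0] for r in informative]
        assert labels.count("paternal") / len(labels) >= 0.95


class TestVoteAcrossK:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (("paternal", "paternal", "undecided", "undecided", "undecided"), "paternal"),
            (("paternal", "paternal", "maternal", "maternal", "undecided"), "unassigned"),
            (("paternal", "undecided", "undecided", "undecided", "undecided"), "unassigned"),
            (("maternal",) * 5, "maternal"),
            (("undecided",) * 5, "unassigned"),
        ],
    )
    def test_rule_examples(self, labels, expected):
        assert vote_across_k(labels) == expected

    def test_exhaustive_truth_table_matches_oracle(self):
        policy = VotingPolicy()
        for labels in itertools.product(LABELS, repeat=5):
            assert vote_across_k(labels, policy) == vote_oracle(labels), labels

    def test_all_ks_basis_truth_table(self):
        policy = VotingPolicy(majority_basis="all_ks")
        for labels in itertools.product(LABELS, repeat=5):
            assert vote_across_k(labels, policy) == vote_oracle(labels, all_ks=True), labels

    def test_min_agreeing_tightens_assignment(self):
        win = ("paternal", "paternal", "undecided", "undecided", "undecided")
        assert vote_across_k(win, VotingPolicy(min_agreeing=2)) == "paternal"
        assert vote_across_k(win, VotingPolicy(min_agreeing=3)) == "unassigned"


class TestPartitionReads:
    def test_empty_input_gives_three_empty_bins(self, small_binning):
        res = partition_reads([], small_binning["indices"], small_binning["policy"])
        assert res.paternal == res.maternal == res.unassigned == []

    def test_bins_partition_the_input(self, small_binning):
        res = small_binning["result"]
        reads = small_binning["reads"]
        assert len(res.paternal) + len(res.maternal) + len(res.unassigned) == len(reads)
        ids = {r.id for r in res.paternal} | {r.id for r in res.maternal} | {
            r.id for r in res.unassigned
        }
        assert len(ids) == len(reads)

    def test_misassignment_rate_is_low(self, small_binning):
        res = small_binning["result"]
        wrong = sum(1 for r in res.paternal if r.origin != "paternal") + sum(
            1 for r in res.maternal if r.origin != "maternal"
        )
        assigned = len(res.paternal) + len(res.maternal)
        assert assigned > 0
        assert wrong / assigned <= 0.01

    def test_shared_region_reads_stay_unassigned(self, small_trio, small_binning):
        # reads fully inside the homozygous-identical region carry no markers
        res = small_binning["result"]
        shared_end = small_trio.shared_regions.intervals[0][2]
        inside = [
            r
            for r in small_binning["reads"]
            if r.start + len(r.seq) <= shared_end
        ]
        if inside:
            unassigned_ids = {r.id for r in res.unassigned}
            frac = sum(1 for r in inside if r.id in unassigned_ids) / len(inside)
            assert frac >= 0.9

    def test_parent_swap_swaps_bins_exactly(self, small_binning):
        indices = small_binning["indices"]
        swapped = {k: v.swapped() for k, v in indices.items()}
        res = small_binning["result"]
        res_sw = partition_reads(
            small_binning["reads"], swapped, small_binning["policy"]
        )
        assert [r.id for r in res.paternal] == [r.id for r in res_sw.maternal]
        assert [r.id for r in res.maternal] == [r.id for r in res_sw.paternal]
        assert [r.id for r in res.unassigned] == [r.id for r in res_sw.unassigned]

    def test_assigned_fraction_monotone_in_min_agreeing(self, small_binning):
        fracs = []
        for m in (1, 2, 3, 4, 5):
            res = partition_reads(
                small_binning["reads"],
                small_binning["indices"],
                VotingPolicy(min_agreeing=m),
            )
            fracs.append(res.assigned_fraction)
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
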