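"""Masking, concatenation, LogDet distances, NJ, bootstrap, monophyly."""

import numpy as np
import pytest

from conftest import random_binary_tree
from darkbin import synth, trees
from darkbin.phylo import (
    AlignmentBlock,
    DistanceMatrix,
    SaturatedDistanceError,
    Supermatrix,
    bootstrap_support,
    concatenate,
    distance_matrix,
    logdet_distance,
    mask_alignment,
    mismatch_distance,
    neighbor_joining,
)


class TestMasking:
    def test_over_gapped_column_removed(self):
        block = AlignmentBlock(
            "m", {"a": "A-", "b": "-C", "c": "-G", "d": "-T"}
        )  # col 0 gapped in 3/4
        masked = mask_alignment(block, max_gap_fraction=0.5)
        assert masked.length == 1
        assert masked.sequences["a"] == "-"

    def test_half_gapped_column_retained(self):
        # gap fraction exactly 0.5: "more than half" is strict, so keep
        block = AlignmentBlock("m", {"a": "A", "b": "C", "c": "-", "d": "-"})
        masked = mask_alignment(block, max_gap_fraction=0.5)
        assert masked.length == 1

    def test_ungapped_alignment_unchanged(self):
        block = AlignmentBlock("m", {"a": "ACGT", "b": "ACGA"})
        masked = mask_alignment(block)
        assert masked.sequences == {"a": "ACGT", "b": "ACGA"}

    def test_all_ambiguous_column_removed(self):
        block = AlignmentBlock("m", {"a": "NA", "b": "NC"})
        masked = mask_alignment(block, molecule="nt")
        assert masked.length == 1

    def test_empty_result_warns(self):
        block = AlignmentBlock("m", {"a": "-", "b": "-", "c": "A"})
        with pytest.warns(UserWarning, match="every column"):
            masked = mask_alignment(block, max_gap_fraction=0.5)
        assert masked.length == 0


class TestConcatenate:
    def test_coordinate_map(self):
        b1 = AlignmentBlock("b1", {"g1": "A" * 10, "g2": "C" * 10})
        b2 = AlignmentBlock("b2", {"g1": "G" * 20, "g2": "T" * 20})
        sm = concatenate([b1, b2], ["g1", "g2"])
        assert sm.length == 30
        assert sm.block_map == {"b1": (0, 10), "b2": (10, 30)}

    def test_missing_genome_padded_with_gaps(self):
        b1 = AlignmentBlock("b1", {"g1": "ACGTACGTAC", "g2": "ACGTACGTAC"})
        b2 = AlignmentBlock("b2", {"g1": "G" * 20})
        sm = concatenate([b1, b2], ["g1", "g2"])
        assert sm.sequences["g2"][10:30] == "-" * 20

    def test_empty_block_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate([], ["g1"])

    def test_duplicate_marker_ids_rejected(self):
        b = AlignmentBlock("b1", {"g1": "A"})
        with pytest.raises(ValueError, match="duplicate"):
            concatenate([b, b], ["g1"])


class TestLogDet:
    def test_identical_balanced_sequences_have_zero_distance(self):
        s = "ACGT" * 25
        assert logdet_distance(s, s) == 0.0

    def test_columns_with_gaps_excluded(self):
        assert logdet_distance("ACGT-ACGT", "ACGTTACGT") == 0.0

    def test_consistent_under_symmetric_model(self):
        # mean estimate near the true distance 0.1 on long simulated pairs
        tree = trees.parse_newick("(A:0.05,B:0.05);")
        estimates = []
        for seed in range(10):
            aln = synth.evolve_alignment(tree, 100_000, seed=seed)
            estimates.append(logdet_distance(aln.sequences["A"], aln.sequences["B"]))
        assert abs(np.mean(estimates) - 0.1) < 0.01

    def test_missing_base_saturates(self):
        # x lacks T entirely: marginal frequency zero
        assert np.isnan(logdet_distance("ACGACG", "ACGTAC"))

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            logdet_distance("AC--", "--GT")

    def test_saturated_pair_fails_matrix_build_with_pair_list(self):
        seqs = {"a": "ACGACG", "b": "ACGTAC", "c": "ACGTGA"}
        with pytest.raises(SaturatedDistanceError) as err:
            distance_matrix(seqs)
        assert ("a", "b") in err.value.pairs

    def test_mismatch_distance_fallback(self):
        assert mismatch_distance("AAAA", "AAAT", canon="ACGT") == pytest.approx(0.25)


class TestNeighborJoining:
    def test_recovers_quartet_with_exact_branch_lengths(self):
        labels = list("ABCD")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(labels=labels, values=d))
        splits = trees.bipartitions(tree)
        assert frozenset("AB") in splits  # AB|CD resolved
        _, dhat = trees.patristic_matrix(tree)
        assert np.allclose(dhat, d)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=list("ABC"), values=d))
        _, dhat = trees.patristic_matrix(tree)
        assert np.allclose(dhat, d)

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 11))
            source = random_binary_tree([f"L{i}" for i in range(n)], rng)
            labels, d = trees.patristic_matrix(source)
            recovered = neighbor_joining(DistanceMatrix(labels=labels, values=d))
            assert set(trees.bipartitions(recovered)) == set(trees.bipartitions(source))
            _, dhat = trees.patristic_matrix(recovered)
            assert np.allclose(dhat, d, atol=1e-9)

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        source = random_binary_tree([f"L{i}" for i in range(8)], rng)
        labels, d = trees.patristic_matrix(source)
        ours = neighbor_joining(DistanceMatrix(labels=labels, values=d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        n = len(labels)
        all_leaves = frozenset(labels)
        their_splits = set()
        for node in theirs.non_tips(include_self=True):
            below = frozenset(t.name for t in node.tips())
            key = trees.canonical_split(below, all_leaves)
            if 2 <= len(key) <= n - 2:
                their_splits.add(key)
        our_splits = {s for s in trees.bipartitions(ours) if 2 <= len(s) <= n - 2}
        assert our_splits == their_splits

    def test_ultrametric_tie_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=list("ABCD"), values=d)
        t1 = neighbor_joining(dm).as_string(schema="newick")
        t2 = neighbor_joining(dm).as_string(schema="newick")
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]]))


class TestBootstrap:
    def make_supermatrix(self, seed=0, length=2000, bl=0.12):
        tax = synth.make_taxonomy(8, 2, 2, 2)
        tree = synth.simulate_gene_tree(tax, congruence=1.0, seed=seed, branch_length=bl)
        aln = synth.evolve_alignment(tree, length, seed=seed)
        return Supermatrix(sequences=aln.sequences, block_map={"m": (0, length)}), tree

    def test_single_replicate_supports_are_binary(self):
        sm, _ = self.make_supermatrix()
        boot = bootstrap_support(sm, n_replicates=1, seed=5)
        assert set(boot.supports.values()) <= {0, 100}

    def test_same_seed_identical_supports(self):
        sm, _ = self.make_supermatrix()
        a = bootstrap_support(sm, n_replicates=20, seed=9)
        b = bootstrap_support(sm, n_replicates=20, seed=9)
        assert a.supports == b.supports

    def test_saturated_signal_gives_high_support(self):
        sm, source = self.make_supermatrix(length=10_000)
        boot = bootstrap_support(sm, n_replicates=30, seed=2)
        assert boot.n_skipped == 0
        assert set(trees.bipartitions(boot.tree)) == set(trees.bipartitions(source))
        assert all(v >= 90 for v in boot.supports.values())

    def test_support_grows_with_alignment_length(self):
        def min_support(length):
            vals = []
            for seed in (3, 4, 5):
                sm, _ = self.make_supermatrix(seed=seed, length=length, bl=0.05)
                boot = bootstrap_support(sm, n_replicates=20, seed=seed)
                vals.append(min(boot.supports.values()))
            return np.mean(vals)

        assert min_support(2000) >= min_support(100)


class TestMonophyly:
    def test_internal_edge_side_is_monophyletic(self):
        t = trees.parse_newick("((A,B),(C,D));")
        assert trees.is_monophyletic(t, {"A", "B"})

    def test_straddling_group_is_not(self):
        t = trees.parse_newick("((A,B),(C,D));")
        assert not trees.is_monophyletic(t, {"A", "C"})

    def test_all_but_one_leaf_is_monophyletic(self):
        t = trees.parse_newick("((A,B),(C,D));")
        assert trees.is_monophyletic(t, {"A", "B", "C"})

    def test_empty_group_rejected(self):
        t = trees.parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            trees.is_monophyletic(t, set())
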