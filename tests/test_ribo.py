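"""16S read-pair filtering, patristic distances, greedy reference clustering."""

import numpy as np
import pytest

from conftest import random_binary_tree
from darkbin import synth, trees
from darkbin.ribo import (
    ReadMapping,
    ReadPairMapping,
    filter_pairs,
    greedy_cluster,
    emit_clusters,
    lineage_abundance,
    pair_concordance,
    pairs_by_reference,
    read_filter,
    read_mappings,
    write_mappings,
)


def mapping(ref="r1", read_len=100, aligned_frac=0.9, edit_distance=5):
    return ReadMapping(ref, read_len, aligned_frac, edit_distance)


class TestReadFilter:
    @pytest.mark.parametrize(
        "aligned_frac,edit_distance,verdict",
        [
            (0.90, 9, True),  # "less than 10 for 100 bp reads"
            (0.90, 10, False),  # strict edit bound
            (0.84, 0, False),  # aligned-fraction threshold
            (0.85, 0, True),  # aligned-fraction bound is inclusive
        ],
    )
    def test_default_thresholds(self, aligned_frac, edit_distance, verdict):
        m = mapping(aligned_frac=aligned_frac, edit_distance=edit_distance)
        assert read_filter(m) is verdict

    def test_monotone_in_thresholds(self, rng):
        for _ in range(200):
            m = mapping(
                aligned_frac=float(rng.uniform(0, 1)),
                edit_distance=int(rng.integers(0, 30)),
            )
            if not read_filter(m, 0.85, 0.10):
                assert not read_filter(m, 0.90, 0.10)
                assert not read_filter(m, 0.85, 0.05)


class TestPatristic:
    def test_same_leaf_is_zero(self):
        t = trees.parse_newick("(A:0.01,B:0.015);")
        assert trees.patristic_distance(t, "A", "A") == 0.0

    def test_cherry_path_sum(self):
        t = trees.parse_newick("((A:0.01,B:0.015):0.5,C:0.2);")
        assert trees.patristic_distance(t, "A", "B") == pytest.approx(0.025)

    def test_matches_path_sum_oracle_on_random_tree(self, rng):
        tree = random_binary_tree([f"L{i}" for i in range(20)], rng)
        labels, d = trees.patristic_matrix(tree)

        # oracle: root-to-leaf depths minus twice the LCA depth
        depth, parent = {}, {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + node.edge.length
            parent[node] = node.parent_node
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

        def lca(a, b):
            seen = set()
            while a is not None:
                seen.add(id(a))
                a = parent[a]
            while id(b) not in seen:
                b = parent[b]
            return b

        for i, la in enumerate(labels):
            for j, lb in enumerate(labels):
                if i < j:
                    anc = lca(leaves[la], leaves[lb])
                    expect = depth[leaves[la]] + depth[leaves[lb]] - 2 * depth[anc]
                    assert d[i, j] == pytest.approx(expect)

    def test_unknown_leaf_rejected(self):
        t = trees.parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            trees.patristic_distance(t, "A", "Z")


class TestPairConcordance:
    # star tree: d(a,b)=0.02, d(a,c)=0.05
    TREE = "(a:0.01,b:0.01,c:0.04);"

    def pair(self, r1, r2):
        return ReadPairMapping("p1", mapping(ref=r1), mapping(ref=r2))

    def test_same_reference_passes(self):
        t = trees.parse_newick(self.TREE)
        assert pair_concordance(self.pair("a", "a"), t, radius=0.03)

    def test_radius_boundary(self):
        t = trees.parse_newick(self.TREE)
        assert pair_concordance(self.pair("a", "b"), t, radius=0.03)
        assert not pair_concordance(self.pair("a", "c"), t, radius=0.03)

    def test_missing_reference_warns_and_fails(self):
        t = trees.parse_newick(self.TREE)
        with pytest.warns(UserWarning, match="absent"):
            assert not pair_concordance(self.pair("a", "zz"), t, radius=0.03)


class TestGreedyCluster:
    def test_hand_traced_example(self):
        # d(r1,r2)=0.02, d(r1,r3)=0.05, d(r2,r3)=0.04
        t = trees.parse_newick("(r1:0.015,r2:0.005,r3:0.035);")
        clusters = greedy_cluster({"r1": 5, "r2": 3, "r3": 1}, t, radius=0.03)
        assert [sorted(c.member_refs) for c in clusters] == [["r1", "r2"], ["r3"]]
        assert [c.n_pairs for c in clusters] == [8, 1]

    def test_everything_within_radius_is_one_cluster(self):
        t = trees.parse_newick("(r1:0.001,r2:0.001,r3:0.001);")
        clusters = greedy_cluster({"r1": 2, "r2": 2, "r3": 2}, t, radius=0.03)
        assert len(clusters) == 1

    def test_zero_radius_gives_one_cluster_per_reference(self):
        t = trees.parse_newick("(r1:0.01,r2:0.02,r3:0.03);")
        clusters = greedy_cluster({"r1": 1, "r2": 1, "r3": 1}, t, radius=0.0)
        assert len(clusters) == 3

    def test_clusters_partition_the_pairs(self, rng):
        tree = random_binary_tree([f"R{i}" for i in range(12)], rng, bl_range=(0.005, 0.05))
        assignments = {
            f"R{i}": [f"p{i}_{k}" for k in range(int(rng.integers(1, 6)))]
            for i in range(12)
        }
        clusters = greedy_cluster(assignments, tree, radius=0.03)
        emitted = [pid for c in clusters for pid in c.pair_ids]
        expected = sorted(p for v in assignments.values() for p in v)
        assert sorted(emitted) == expected
        assert len(emitted) == len(set(emitted))

    def test_cluster_count_non_increasing_in_radius(self, rng):
        tree = random_binary_tree([f"R{i}" for i in range(15)], rng, bl_range=(0.005, 0.05))
        assignments = {f"R{i}": int(rng.integers(1, 10)) for i in range(15)}
        counts = [
            len(greedy_cluster(assignments, tree, radius=r))
            for r in (0.0, 0.01, 0.03, 0.1, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_recovers_planted_sources(self, k):
        # sources pairwise separated by > 2x radius; placement noise off
        tax = synth.make_taxonomy(20, 1, 2, 4, prefix="R")
        tree = synth.simulate_gene_tree(tax, congruence=1.0, seed=3, branch_length=0.1)
        labels = trees.leaf_labels(tree)
        step = len(labels) // k
        sources = [labels[i * step] for i in range(k)]
        pairs = []
        for src in sources:
            pairs.extend(
                synth.simulate_read_pairs(tree, src, 10, placement_sd=0.0, seed=7)
            )
        clusters = greedy_cluster(pairs_by_reference(pairs), tree, radius=0.03)
        assert len(clusters) == k
        assert sorted(c.seed_ref for c in clusters) == sorted(sources)


class TestEmitAndAbundance:
    def make_clusters(self):
        t = trees.parse_newick("(r1:0.015,r2:0.005,r3:0.035);")
        assignments = {
            "r1": [f"p{i}" for i in range(5)],
            "r2": [f"q{i}" for i in range(3)],
            "r3": ["z0"],
        }
        return greedy_cluster(assignments, t, radius=0.03)

    def test_interleaved_files_and_manifest(self, tmp_path):
        clusters = self.make_clusters()
        reads = {pid: ("ACGT", "TTTT") for c in clusters for pid in c.pair_ids}
        manifest = emit_clusters(clusters, reads, tmp_path)
        assert manifest["n_reads"].tolist() == [16, 2]
        fasta = (tmp_path / manifest.loc[0, "fasta"]).read_text()
        assert fasta.count(">") == 16

    def test_missing_reads_rejected(self, tmp_path):
        clusters = self.make_clusters()
        with pytest.raises(KeyError, match="p0"):
            emit_clusters(clusters, {}, tmp_path)

    def test_duplicate_pair_across_clusters_rejected(self, tmp_path):
        clusters = self.make_clusters()
        dup = [clusters[0], clusters[0]]
        reads = {pid: ("A", "C") for c in clusters for pid in c.pair_ids}
        with pytest.raises(ValueError, match="more than one cluster"):
            emit_clusters(dup, reads, tmp_path)

    def test_lineage_fractions(self):
        clusters = self.make_clusters()
        lineage = {"r1": "target", "r3": "other"}
        fractions = lineage_abundance(clusters, lineage)
        assert fractions["target"] == pytest.approx(8 / 9)
        assert fractions["other"] == pytest.approx(1 / 9)

    def test_no_pairs_warns_empty(self):
        with pytest.warns(UserWarning, match="no surviving pairs"):
            assert lineage_abundance([], {}) == {}


class TestFilterPipelineAndIO:
    def test_filter_pairs_tallies_causes(self):
        t = trees.parse_newick("(a:0.01,b:0.01,c:0.04);")
        good = ReadPairMapping("g", mapping(ref="a"), mapping(ref="b"))
        bad_read = ReadPairMapping("br", mapping(ref="a", aligned_frac=0.5), mapping(ref="a"))
        bad_pair = ReadPairMapping("bp", mapping(ref="a"), mapping(ref="c"))
        surviving, stats = filter_pairs([good, bad_read, bad_pair], t)
        assert [p.pair_id for p in surviving] == ["g"]
        assert stats == {
            "input": 3,
            "failed_read_filter": 1,
            "failed_concordance": 1,
            "surviving": 1,
        }

    def test_mapping_tsv_round_trip(self, tmp_path):
        pairs = [
            ReadPairMapping("p1", mapping(ref="a"), mapping(ref="b", edit_distance=2)),
            ReadPairMapping("p2", mapping(ref="c"), mapping(ref="c")),
        ]
        path = tmp_path / "maps.tsv"
        write_mappings(pairs, path)
        assert read_mappings(path) == pairs
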