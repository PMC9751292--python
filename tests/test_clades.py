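"""Clade partitioning: worked examples, invariants, and a brute-force oracle."""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
import pytest

from cldkit.clades import (
    load_tree,
    mean_leaf_distances,
    partition_by_mean_distance,
    summarize_clades,
)
from cldkit.errors import FormatError, MissingIdError
from cldkit.synthetic import random_tree

FOUR_LEAF = "((A:1,B:1):1,(C:3,D:3):1);"


def brute_force_partition(newick: str, threshold: float) -> list[frozenset[str]]:
    """Independent oracle: compute every node's mean leaf distance by summing
    explicit root-to-leaf paths, then greedily select the highest qualifying
    nodes in pre-order."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        rooting="default-rooted",
    )
    means = {}
    for node in tree.preorder_node_iter():
        leaves = [leaf for leaf in node.leaf_iter()]
        total = 0.0
        for leaf in leaves:
            # walk up from leaf to node, summing edge lengths
            cursor = leaf
            while cursor is not node:
                total += cursor.edge.length or 0.0
                cursor = cursor.parent_node
        means[node] = total / len(leaves)

    clades = []

    def walk(node):
        if means[node] <= threshold or not node.child_nodes():
            clades.append(
                frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            )
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    return clades


class TestExamples:
    def test_threshold_above_depth_gives_single_clade(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 100)
        assert len(partition.clades) == 1
        assert partition.clades[0].leaf_ids == frozenset("ABCD")

    def test_threshold_zero_gives_singletons(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 0)
        assert sorted(c.leaf_ids for c in partition.clades) == [
            frozenset("A"), frozenset("B"), frozenset("C"), frozenset("D"),
        ]

    def test_hand_computed_four_leaf_partition(self):
        # cherry (A,B) has mean 1 <= 2; cherry (C,D) has mean 3 > 2
        partition = partition_by_mean_distance(FOUR_LEAF, 2)
        clades = sorted(sorted(c.leaf_ids) for c in partition.clades)
        assert clades == [["A", "B"], ["C"], ["D"]]

    def test_clade_ids_follow_preorder_discovery(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 2)
        by_id = {c.clade_id: sorted(c.leaf_ids) for c in partition.clades}
        assert by_id == {1: ["A", "B"], 2: ["C"], 3: ["D"]}

    def test_strict_comparison_differs_only_at_equality(self):
        newick = "((A:1,B:1):1,C:5);"  # cherry mean is exactly 1
        inclusive = partition_by_mean_distance(newick, 1, inclusive=True)
        strict = partition_by_mean_distance(newick, 1, inclusive=False)
        assert frozenset("AB") in {c.leaf_ids for c in inclusive.clades}
        assert frozenset("AB") not in {c.leaf_ids for c in strict.clades}


class TestFormatErrors:
    def test_lengthless_tree_rejected(self):
        with pytest.raises(FormatError, match="length"):
            partition_by_mean_distance("((A,B),C);", 1)

    def test_explicitly_unrooted_tree_rejected(self):
        with pytest.raises(FormatError, match="unrooted"):
            partition_by_mean_distance("[&U] ((A:1,B:1):1,C:2);", 1)

    def test_multifurcations_and_zero_lengths_allowed(self):
        partition = partition_by_mean_distance("(A:0,B:0,C:1):0;", 0.5)
        assert partition.leaf_ids == frozenset("ABC")


class TestInvariantsAndOracle:
    @pytest.mark.parametrize("seed", range(40))
    def test_partition_invariants_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        newick = random_tree([f"L{i}" for i in range(n)], rng)
        threshold = float(rng.uniform(0, 0.5))
        partition = partition_by_mean_distance(newick, threshold)
        # disjoint cover
        all_leaves = [leaf for c in partition.clades for leaf in c.leaf_ids]
        assert len(all_leaves) == len(set(all_leaves)) == n
        # threshold: every multi-leaf clade's node qualifies
        for clade in partition.clades:
            if clade.size > 1:
                assert clade.mean_leaf_distance <= threshold
        # maximality: no emitted node's parent qualifies
        tree = load_tree(newick)
        means = mean_leaf_distances(tree)
        leafset_to_node = {
            frozenset(l.taxon.label for l in node.leaf_iter()): node
            for node in tree.preorder_node_iter()
        }
        for clade in partition.clades:
            node = leafset_to_node[clade.leaf_ids]
            if node.parent_node is not None:
                assert means[node.parent_node] > threshold

    @pytest.mark.parametrize("seed", range(30))
    def test_agreement_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 33))
        newick = random_tree([f"L{i}" for i in range(n)], rng)
        threshold = float(rng.uniform(0, 0.4))
        ours = {c.leaf_ids for c in partition_by_mean_distance(newick, threshold).clades}
        oracle = set(brute_force_partition(newick, threshold))
        assert ours == oracle

    def test_clade_count_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(7)
        newick = random_tree([f"L{i}" for i in range(30)], rng)
        counts = [
            len(partition_by_mean_distance(newick, t).clades)
            for t in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1


class TestSummaries:
    def annotations(self):
        return pd.DataFrame(
            {
                "protein_id": ["A", "B", "C", "D"],
                "genus": ["Azospira", "Azospira", "Nitrospira", "Ideonella"],
                "source": ["genomic", "metagenomic", "genomic", "genomic"],
                "sequence": ["MKWE", "MKWE", "MQWE", "MRW-"],
                "length": [100, 200, 150, 120],
            }
        )

    def test_single_genus_clade(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 2)
        summary = summarize_clades(partition, self.annotations()).set_index("clade_id")
        assert summary.loc[1, "n_genera"] == 1
        assert not summary.loc[1, "cross_genus_identical"]

    def test_identical_sequence_across_genera_not_within(self):
        # A and B share a sequence but one genus -> false; planting the same
        # sequence on C (another genus) inside one clade flips it
        ann = self.annotations()
        partition = partition_by_mean_distance(FOUR_LEAF, 100)  # one clade
        summary = summarize_clades(partition, ann)
        assert not summary.loc[0, "cross_genus_identical"]
        ann.loc[ann["protein_id"] == "C", "sequence"] = "MKWE"
        summary = summarize_clades(partition, ann)
        assert summary.loc[0, "cross_genus_identical"]

    def test_length_statistics(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 2)
        summary = summarize_clades(partition, self.annotations()).set_index("clade_id")
        assert summary.loc[1, "length_mean"] == 150
        assert summary.loc[1, "length_min"] == 100
        assert summary.loc[1, "length_max"] == 200

    def test_counts_by_source(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 2)
        summary = summarize_clades(partition, self.annotations()).set_index("clade_id")
        assert summary.loc[1, "n_genomic"] == 1
        assert summary.loc[1, "n_metagenomic"] == 1

    def test_missing_annotation_names_leaf(self):
        partition = partition_by_mean_distance(FOUR_LEAF, 2)
        with pytest.raises(MissingIdError, match="D"):
            summarize_clades(partition, self.annotations().iloc[:3])

    def test_cross_genus_detected_in_synthetic_truth(self, small_dataset):
        """The planted identical cross-genus Cld pair must surface in the
        summary of a one-clade partition."""
        ds = small_dataset
        partition = partition_by_mean_distance(ds.tree_newick, 1e9)
        genes = ds.genes.set_index("protein_id")
        ann = pd.DataFrame(
            {
                "protein_id": list(ds.truth.anchor_protein_ids),
                "genus": [
                    genes.loc[p, "genus"] for p in ds.truth.anchor_protein_ids
                ],
                "source": "genomic",
                "sequence": [
                    ds.proteins[p] for p in ds.truth.anchor_protein_ids
                ],
            }
        )
        summary = summarize_clades(partition, ann)
        assert summary.loc[0, "cross_genus_identical"]
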