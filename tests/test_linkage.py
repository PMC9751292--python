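"""Co-occurrence network construction and the clustering-coefficient statistic."""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from cldkit.errors import MissingIdError, ParameterError
from cldkit.linkage import (
    build_network,
    clustering_coefficient,
    clustering_coefficients,
    rank_linkage,
)
from cldkit.neighborhoods import Neighborhood, extract_neighborhoods
from conftest import truth_assignment


def make_neighborhood(nid, subfamily_ids):
    """Neighborhood whose proteins map 1:1 onto the given subfamily ids."""
    n = len(subfamily_ids)
    offsets = tuple(range(-(n // 2), n - n // 2))
    return (
        Neighborhood(
            neighborhood_id=nid,
            anchor_gene_id=f"{nid}_anchor",
            contig_id=nid,
            genome_id=nid,
            offsets=offsets,
            gene_ids=tuple(f"{nid}_g{i}" for i in range(n)),
            protein_ids=tuple(f"{nid}_p{i}" for i in range(n)),
        ),
        {f"{nid}_p{i}": sid for i, sid in enumerate(subfamily_ids)},
    )


def brute_force_cc(graph: nx.Graph, node) -> Fraction:
    """Independent oracle: enumerate neighbor pairs and count realized edges."""
    neighbors = sorted(graph.adj[node])
    if len(neighbors) < 2:
        return Fraction(0)
    edges = sum(
        1 for u, v in itertools.combinations(neighbors, 2) if graph.has_edge(u, v)
    )
    possible = len(neighbors) * (len(neighbors) - 1) // 2
    return Fraction(edges, possible)


class TestNetworkConstruction:
    def test_single_neighborhood_gives_complete_graph(self):
        nbh, mapping = make_neighborhood("n0", ["A", "B", "C"])
        graph = build_network([nbh], mapping)
        assert set(graph.nodes) == {"A", "B", "C"}
        assert graph.number_of_edges() == 3

    def test_disjoint_neighborhoods_give_disjoint_edges(self):
        n0, m0 = make_neighborhood("n0", ["A", "B"])
        n1, m1 = make_neighborhood("n1", ["C", "D"])
        graph = build_network([n0, n1], {**m0, **m1})
        assert set(graph.edges) == {("A", "B"), ("C", "D")} or set(
            map(frozenset, graph.edges)
        ) == {frozenset("AB"), frozenset("CD")}

    def test_repeated_subfamily_in_one_neighborhood_no_self_loop(self):
        nbh, mapping = make_neighborhood("n0", ["A", "A", "B"])
        graph = build_network([nbh], mapping)
        assert "A" in graph
        assert not any(u == v for u, v in graph.edges)
        assert graph.nodes["A"]["occurrence"] == 1

    def test_occurrence_counts_neighborhoods_not_genes(self):
        n0, m0 = make_neighborhood("n0", ["A", "B"])
        n1, m1 = make_neighborhood("n1", ["A", "C"])
        graph = build_network([n0, n1], {**m0, **m1})
        assert graph.nodes["A"]["occurrence"] == 2
        assert graph.nodes["B"]["occurrence"] == 1

    def test_min_count_filters_rare_edges(self):
        n0, m0 = make_neighborhood("n0", ["A", "B"])
        n1, m1 = make_neighborhood("n1", ["A", "B"])
        n2, m2 = make_neighborhood("n2", ["A", "C"])
        graph = build_network([n0, n1, n2], {**m0, **m1, **m2}, min_count=2)
        assert graph.has_edge("A", "B")
        assert not graph.has_edge("A", "C")

    def test_unassigned_protein_named_in_error(self):
        nbh, mapping = make_neighborhood("n0", ["A", "B"])
        del mapping["n0_p1"]
        with pytest.raises(MissingIdError, match="n0_p1"):
            build_network([nbh], mapping)


class TestClusteringCoefficient:
    def test_triangle_node_is_one(self):
        graph = nx.complete_graph(["A", "B", "C"])
        assert clustering_coefficient(graph, "A") == 1

    def test_path_center_is_zero(self):
        graph = nx.path_graph(["A", "B", "C"])
        assert clustering_coefficient(graph, "B") == 0

    def test_four_neighbors_three_edges_is_half(self):
        graph = nx.Graph()
        graph.add_edges_from([("x", n) for n in "ABCD"])
        graph.add_edges_from([("A", "B"), ("B", "C"), ("C", "D")])
        assert clustering_coefficient(graph, "x") == Fraction(1, 2)

    def test_degree_below_two_is_zero(self):
        graph = nx.path_graph(["A", "B"])
        assert clustering_coefficient(graph, "A") == 0

    def test_unknown_node_rejected(self):
        with pytest.raises(MissingIdError):
            clustering_coefficient(nx.Graph(), "ghost")

    @pytest.mark.parametrize("seed", range(60))
    def test_exact_agreement_with_triangle_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 31))
        graph = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.9)), seed=seed)
        ours = clustering_coefficients(graph)
        for node in graph.nodes:
            assert ours[node] == brute_force_cc(graph, node)
            assert ours[node] == clustering_coefficient(graph, node)

    def test_agreement_with_networkx(self):
        graph = nx.gnp_random_graph(40, 0.2, seed=7)
        ours = clustering_coefficients(graph)
        theirs = nx.clustering(graph)
        for node in graph.nodes:
            assert abs(float(ours[node]) - theirs[node]) < 1e-12

    def test_invariant_under_relabeling(self):
        graph = nx.gnp_random_graph(25, 0.3, seed=3)
        relabeled = nx.relabel_nodes(graph, {n: f"node_{n}" for n in graph.nodes})
        ours = clustering_coefficients(graph)
        theirs = clustering_coefficients(relabeled)
        for node in graph.nodes:
            assert ours[node] == theirs[f"node_{node}"]


class TestRanking:
    def test_sorted_ascending_with_id_tie_break(self):
        n0, m0 = make_neighborhood("n0", ["A", "B", "C"])
        n1, m1 = make_neighborhood("n1", ["A", "D"])
        graph = build_network([n0, n1], {**m0, **m1})
        table = rank_linkage(graph)
        ccs = list(table["clustering_coefficient"])
        assert ccs == sorted(ccs)
        ties = table[table["clustering_coefficient"] == ccs[0]]
        assert list(ties["subfamily_id"]) == sorted(ties["subfamily_id"])

    def test_exact_threshold_is_not_a_hit(self):
        # star center with 5 neighbors carrying exactly 1 edge among them:
        # CC = 1/10 = threshold -> strict inequality excludes it
        graph = nx.star_graph(["x", "A", "B", "C", "D", "E"])
        graph.add_edge("A", "B")
        table = rank_linkage(graph, hit_threshold=0.1).set_index("subfamily_id")
        assert table.loc["x", "clustering_coefficient"] == 0.1
        assert not table.loc["x", "hit"]

    def test_below_threshold_is_a_hit(self):
        graph = nx.star_graph(["x", "A", "B", "C", "D", "E"])
        table = rank_linkage(graph, hit_threshold=0.1).set_index("subfamily_id")
        assert table.loc["x", "hit"]

    def test_empty_network_empty_table(self):
        table = rank_linkage(nx.Graph())
        assert table.empty

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            rank_linkage(nx.Graph(), hit_threshold=1.5)


class TestPlantedRecovery:
    def test_shared_subfamily_scores_below_archetype_exclusives(
        self, archetype_dataset
    ):
        """Two archetypes share only the planted 'linked' subfamily (and the
        anchor itself); spanning both context types must drive its clustering
        coefficient below the median of archetype-exclusive subfamilies."""
        ds = archetype_dataset
        nbhs = extract_neighborhoods(ds.genes, ds.truth.anchor_gene_ids)
        graph = build_network(nbhs, truth_assignment(ds))
        ccs = {n: float(c) for n, c in clustering_coefficients(graph).items()}
        exclusives = [
            ccs[sid]
            for sid in ccs
            if sid.startswith("A") or sid.startswith("B")
        ]
        assert ccs["linked"] < float(np.median(exclusives))

    def test_clique_addition_never_lowers_outside_coefficients(self):
        n0, m0 = make_neighborhood("n0", ["A", "B", "C", "D"])
        n1, m1 = make_neighborhood("n1", ["C", "D", "E"])
        graph = build_network([n0, n1], {**m0, **m1})
        before = clustering_coefficients(graph)
        # add a neighborhood whose subfamilies already form a clique
        n2, m2 = make_neighborhood("n2", ["A", "B", "C"])
        graph_after = build_network([n0, n1, n2], {**m0, **m1, **m2})
        after = clustering_coefficients(graph_after)
        for node in ("E",):  # outside the added clique
            assert after[node] >= before[node]
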