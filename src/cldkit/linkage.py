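"""Subfamily co-occurrence network and the clustering-coefficient linkage
statistic.

Each subfamily found in any genomic neighborhood is one node; an edge joins two
subfamilies found together in at least one neighborhood. The linkage statistic
for a subfamily is its local clustering coefficient: the number of edges among
its neighbors divided by the number of pairs of neighbors. A *low* coefficient
marks a subfamily recurring across many different kinds of neighborhoods —
i.e. one genetically linked to the anchor gene itself rather than co-located by
chance — so subfamilies are ranked ascending and those below a threshold
(default 0.1) are flagged as hits.

Coefficients are computed in exact rational arithmetic and rounded to three
decimals only on output.
"""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import MissingIdError, ParameterError
from .neighborhoods import Neighborhood
from .subfamilies import SubfamilyAssignment

__all__ = [
    "DEFAULT_HIT_THRESHOLD",
    "neighborhood_subfamily_sets",
    "build_network",
    "clustering_coefficient",
    "clustering_coefficients",
    "rank_linkage",
    "write_edge_list",
    "write_graphml",
]

DEFAULT_HIT_THRESHOLD = 0.1


def neighborhood_subfamily_sets(
    neighborhoods: Iterable[Neighborhood],
    assignment: SubfamilyAssignment | Mapping[str, str],
) -> dict[str, frozenset[str]]:
    """Subfamily content of each neighborhood (set-valued; duplicates collapse)."""
    mapping = (
        assignment.membership
        if isinstance(assignment, SubfamilyAssignment)
        else assignment
    )
    sets: dict[str, frozenset[str]] = {}
    for nbh in neighborhoods:
        sids = []
        for pid in nbh.protein_ids:
            if pid not in mapping:
                raise MissingIdError(
                    f"protein {pid!r} in neighborhood {nbh.neighborhood_id!r} "
                    "has no subfamily assignment"
                )
            sids.append(mapping[pid])
        sets[nbh.neighborhood_id] = frozenset(sids)
    return sets


def build_network(
    neighborhoods: Iterable[Neighborhood],
    assignment: SubfamilyAssignment | Mapping[str, str],
    min_count: int = 1,
) -> nx.Graph:
    """Build the subfamily co-occurrence network.

    One node per subfamily occurring in at least one neighborhood, annotated
    with its ``occurrence`` count (number of neighborhoods containing it). An
    undirected edge joins two distinct subfamilies co-occurring in at least
    ``min_count`` neighborhoods (default 1; no minimum is imposed beyond
    that). A subfamily occurring twice in one neighborhood contributes a node
    but never a self-loop.
    """
    if min_count < 1:
        raise ParameterError(f"min_count must be >= 1, got {min_count}")
    sets = neighborhood_subfamily_sets(neighborhoods, assignment)

    graph = nx.Graph()
    pair_counts: dict[tuple[str, str], int] = {}
    for sids in sets.values():
        ordered = sorted(sids)
        for sid in ordered:
            if sid in graph:
                graph.nodes[sid]["occurrence"] += 1
            else:
                graph.add_node(sid, occurrence=1)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    for (a, b), count in pair_counts.items():
        if count >= min_count:
            graph.add_edge(a, b, count=count)
    return graph


def clustering_coefficient(graph: nx.Graph, node: str) -> Fraction:
    """Local clustering coefficient of one node, as an exact fraction.

    With k neighbors and e edges among them, returns e / (k(k-1)/2); nodes
    with fewer than two neighbors return 0 (the usual library convention).
    """
    if node not in graph:
        raise MissingIdError(f"node {node!r} not in network")
    neighbors = set(graph.adj[node])
    k = len(neighbors)
    if k < 2:
        return Fraction(0)
    e = sum(len(set(graph.adj[u]) & neighbors) for u in neighbors) // 2
    return Fraction(e, k * (k - 1) // 2)


def clustering_coefficients(graph: nx.Graph) -> dict[str, Fraction]:
    """Exact local clustering coefficient for every node.

    Single pass over adjacency sets rather than repeated pairwise scans.
    """
    adj = {n: set(graph.adj[n]) for n in graph.nodes}
    out: dict[str, Fraction] = {}
    for node, neighbors in adj.items():
        k = len(neighbors)
        if k < 2:
            out[node] = Fraction(0)
            continue
        e = sum(len(adj[u] & neighbors) for u in neighbors) // 2
        out[node] = Fraction(e, k * (k - 1) // 2)
    return out


def _threshold_fraction(threshold: float) -> Fraction:
    # via the decimal literal so 0.1 means exactly 1/10 at the hit boundary
    return Fraction(Decimal(str(threshold)))


def rank_linkage(
    graph: nx.Graph,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank subfamilies by clustering coefficient, lowest (most linked) first.

    Returns a DataFrame with columns ``subfamily_id``, ``clustering_coefficient``
    (rounded to 3 decimals), ``occurrence`` and ``hit`` (coefficient strictly
    below ``hit_threshold``, judged in exact arithmetic). Ties are broken by
    subfamily id. Optional per-subfamily ``annotations`` (indexed by subfamily
    id; e.g. product/function/length metadata) are passed through by join.
    """
    if not 0 <= hit_threshold <= 1:
        raise ParameterError(
            f"hit_threshold must be in [0, 1], got {hit_threshold}"
        )
    coefficients = clustering_coefficients(graph)
    cutoff = _threshold_fraction(hit_threshold)
    rows = []
    for sid in sorted(coefficients, key=lambda s: (coefficients[s], s)):
        cc = coefficients[sid]
        rows.append(
            {
                "subfamily_id": sid,
                "clustering_coefficient": round(float(cc), 3),
                "occurrence": graph.nodes[sid].get("occurrence", 0),
                "hit": cc < cutoff,
            }
        )
    table = pd.DataFrame(
        rows, columns=["subfamily_id", "clustering_coefficient", "occurrence", "hit"]
    )
    if annotations is not None:
        table = table.join(annotations, on="subfamily_id")
    return table


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("subfamily_a\tsubfamily_b\tcount\n")
        for a, b, data in sorted(graph.edges(data=True)):
            handle.write(f"{a}\t{b}\t{data.get('count', 1)}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
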