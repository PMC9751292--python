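"""Partition a protein tree into clades by mean node-to-leaf distance.

A phylogeny of thousands of Cld proteins is summarised by cutting it into
disjoint clades: walking from the root in pre-order, a node whose mean path
length to its descendant leaves is within a branch-length threshold is emitted
as one clade and not descended into. Leaves reached without any qualifying
ancestor become singleton clades, so the clades always form a disjoint cover
of the leaf set and each emitted node is maximal (its parent exceeds the
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .errors import FormatError, MissingIdError, ParameterError

__all__ = [
    "Clade",
    "CladePartition",
    "load_tree",
    "partition_by_mean_distance",
    "summarize_clades",
]


@dataclass(frozen=True)
class Clade:
    clade_id: int
    leaf_ids: frozenset[str]
    mean_leaf_distance: float

    @property
    def size(self) -> int:
        return len(self.leaf_ids)


@dataclass(frozen=True)
class CladePartition:
    threshold: float
    clades: tuple[Clade, ...] = field(default_factory=tuple)

    @property
    def leaf_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for clade in self.clades:
            out |= clade.leaf_ids
        return frozenset(out)

    def membership(self) -> dict[str, int]:
        """Leaf id -> clade id."""
        return {
            leaf: clade.clade_id for clade in self.clades for leaf in clade.leaf_ids
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade_id": c.clade_id, "leaf_id": leaf}
            for c in self.clades
            for leaf in sorted(c.leaf_ids)
        ]
        return pd.DataFrame(rows, columns=["clade_id", "leaf_id"])


def load_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    """Load a rooted Newick tree with branch lengths.

    Accepts a dendropy Tree, a Newick string, or a path. Trees explicitly
    declared unrooted (``[&U]``) are rejected; plain Newick is treated as
    rooted at its basal node, since the rooting choice belongs to the caller.
    """
    if isinstance(source, dendropy.Tree):
        tree = source
    else:
        text = str(source)
        kwargs = dict(
            schema="newick",
            rooting="default-rooted",
            # keep underscores verbatim: sequence ids are not Newick phrases
            preserve_underscores=True,
        )
        if "(" in text:
            tree = dendropy.Tree.get(data=text, **kwargs)
        else:
            tree = dendropy.Tree.get(path=text, **kwargs)
    if tree.is_rooted is False:
        raise FormatError("tree is explicitly unrooted; clade partition needs a root")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("tree has branches without lengths")
        if edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    return tree


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    if node.label is not None:
        return node.label
    raise FormatError("tree contains an unlabeled leaf")


def mean_leaf_distances(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Mean path length from each node to its descendant leaves.

    Computed in one post-order pass from per-subtree (sum of leaf path
    lengths, leaf count) accumulators.
    """
    sums: dict[dendropy.Node, float] = {}
    counts: dict[dendropy.Node, int] = {}
    means: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            sums[node], counts[node] = 0.0, 1
        else:
            total = 0.0
            n = 0
            for child in children:
                length = child.edge.length or 0.0
                total += sums[child] + length * counts[child]
                n += counts[child]
            sums[node], counts[node] = total, n
        means[node] = sums[node] / counts[node]
    return means


def partition_by_mean_distance(
    tree: str | Path | dendropy.Tree,
    threshold: float,
    *,
    inclusive: bool = True,
) -> CladePartition:
    """Cut a rooted tree into disjoint clades at a mean-distance threshold.

    Pre-order traversal from the root: a node is emitted as one clade when its
    mean distance to descendant leaves is within ``threshold`` (``<=`` by
    default; set ``inclusive=False`` for strict ``<``; the two differ only at
    exact equality), and its subtree is not descended. Leaves reached without
    an emitting ancestor become singleton clades. Clade ids follow pre-order
    discovery rank, starting at 1.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    tree = load_tree(tree)
    means = mean_leaf_distances(tree)

    qualifies = (
        (lambda m: m <= threshold) if inclusive else (lambda m: m < threshold)
    )
    clades: list[Clade] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        is_leaf = not node.child_nodes()
        if qualifies(means[node]) or is_leaf:
            leaves = frozenset(
                _leaf_label(leaf) for leaf in node.leaf_iter()
            )
            clades.append(
                Clade(
                    clade_id=len(clades) + 1,
                    leaf_ids=leaves,
                    mean_leaf_distance=means[node],
                )
            )
        else:
            # reversed: pop order follows the tree's child order (pre-order)
            stack.extend(reversed(node.child_nodes()))
    return CladePartition(threshold=threshold, clades=tuple(clades))


def summarize_clades(
    partition: CladePartition, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-clade summary of protein annotations.

    ``annotations`` is indexed by protein id (or carries a ``protein_id``
    column) with columns among: ``genus``, ``source`` ('genomic' or
    'metagenomic'), ``sequence``, ``length``, ``signal_peptide``,
    ``n_key_residues``, plus optional per-residue boolean columns prefixed
    ``has_`` (e.g. ``has_R127``). Protein length falls back to the ungapped
    sequence length when no ``length`` column is given.

    Each clade row reports membership counts by source, key-residue and
    signal-peptide fractions, length statistics (min, Q1, mean, Q3, max),
    the number of distinct genera, and ``cross_genus_identical`` — true when
    two members share an identical full sequence under distinct genus labels,
    the footprint of very recent horizontal gene transfer.
    """
    if "protein_id" in annotations.columns:
        annotations = annotations.set_index("protein_id")

    rows = []
    for clade in partition.clades:
        missing = [pid for pid in clade.leaf_ids if pid not in annotations.index]
        if missing:
            raise MissingIdError(
                f"no annotations for leaves {sorted(missing)[:5]} "
                f"(clade {clade.clade_id})"
            )
        sub = annotations.loc[sorted(clade.leaf_ids)]
        row: dict = {
            "clade_id": clade.clade_id,
            "n_proteins": len(sub),
            "mean_leaf_distance": clade.mean_leaf_distance,
        }
        if "source" in sub:
            row["n_genomic"] = int((sub["source"] == "genomic").sum())
            row["n_metagenomic"] = int((sub["source"] == "metagenomic").sum())
        for col in sub.columns:
            if col.startswith("has_"):
                row[f"frac_{col[4:]}"] = float(sub[col].mean())
        if "signal_peptide" in sub:
            known = sub["signal_peptide"].dropna()
            row["frac_signal_peptide"] = (
                float(known.astype(bool).mean()) if len(known) else float("nan")
            )
        lengths = None
        if "length" in sub:
            lengths = sub["length"].astype(float)
        elif "sequence" in sub:
            lengths = sub["sequence"].map(
                lambda s: sum(1 for c in s if c not in "-.")
            ).astype(float)
        if lengths is not None:
            row.update(
                length_min=float(lengths.min()),
                length_q1=float(lengths.quantile(0.25)),
                length_mean=float(lengths.mean()),
                length_q3=float(lengths.quantile(0.75)),
                length_max=float(lengths.max()),
            )
        if "genus" in sub:
            row["n_genera"] = int(sub["genus"].nunique())
            cross = False
            if "sequence" in sub:
                for _, grp in sub.groupby("sequence"):
                    if grp["genus"].nunique() > 1:
                        cross = True
                        break
            row["cross_genus_identical"] = cross
        rows.append(row)
    return pd.DataFrame(rows)
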