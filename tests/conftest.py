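"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import pytest

from cldkit.subfamilies import SubfamilyAssignment, assignment_from_truth
from cldkit.synthetic import AssociatedSubfamily, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """25 anchors on 30 contigs with one planted associated subfamily, a 20%
    key-residue knockout rate, and one identical cross-genus Cld pair."""
    config = SynthConfig(
        seed=1,
        n_contigs=30,
        genes_per_contig=40,
        n_anchors=25,
        associated_subfamilies=(AssociatedSubfamily("assocA", 0.9, 3),),
        background_subfamilies=20,
        residue_mutation_rate=0.2,
        cross_genus_identical=True,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def archetype_dataset():
    """Two disjoint 12-subfamily archetypes plus one shared planted subfamily,
    one ±10 window per contig — the planted-linkage benchmark at unit scale."""
    config = SynthConfig(
        seed=5,
        n_contigs=120,
        genes_per_contig=21,
        n_anchors=120,
        associated_subfamilies=(AssociatedSubfamily("linked", 0.95, 3),),
        archetypes=(
            tuple(f"A{i:02d}" for i in range(12)),
            tuple(f"B{i:02d}" for i in range(12)),
        ),
        background_subfamilies=10,
    )
    return generate_dataset(config)


def truth_assignment(dataset) -> SubfamilyAssignment:
    """Subfamily assignment taken directly from planted truth."""
    gene_to_protein = dict(
        zip(dataset.genes["gene_id"], dataset.genes["protein_id"])
    )
    return assignment_from_truth(
        (gene_to_protein[gid], sid)
        for gid, sid in dataset.truth.subfamily_by_gene.items()
    )
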