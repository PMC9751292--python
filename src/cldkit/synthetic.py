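"""Synthetic genomes with planted structure for benchmarking every stage.

The generator emits mutually consistent gene tables (GFF3 + TSV), protein
FASTA, a family alignment, and a tree, together with the ground truth used to
score downstream stages: which genes are *cld* anchors, each gene's true
subfamily, each anchor's neighborhood archetype, and each Cld protein's true
key-residue count.

Planted structure:

- contigs of ordered genes, with anchors spaced so their ±10-gene windows
  never overlap (windows truncate at contig ends when contigs are short);
- *associated* subfamilies placed within a configured offset of each anchor
  with a configured probability — the knob for co-occurrence linkage tests;
- *archetypes*: distinct subfamily repertoires that fill anchor windows, so
  neighborhoods fall into recoverable content groups;
- protein sequences derived from per-subfamily templates by point mutation;
  Cld anchors derive from a fixed Cld-like template whose four catalytic key
  residues are controlled exactly (a configured fraction of anchors loses one
  key residue);
- a genus vocabulary, with an option to plant one identical Cld sequence
  under two genera — the signature of very recent horizontal transfer;
- a random bifurcating tree over anchor proteins with exponential branch
  lengths (only branch-length arithmetic matters downstream, not realism).

All randomness flows from one seed; identical configs give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .identify import DEFAULT_KEY_RESIDUES
from .neighborhoods import GENE_TABLE_COLUMNS

__all__ = [
    "REFERENCE_ID",
    "CLD_TEMPLATE",
    "AssociatedSubfamily",
    "SynthConfig",
    "SynthTruth",
    "SyntheticDataset",
    "generate_dataset",
    "random_tree",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_INDEX = {aa: i for i, aa in enumerate(_AA)}

REFERENCE_ID = "Nwinogradskyi_Nb255_Cld"

CLD_TEMPLATE_LENGTH = 250

#: Background mutation rate applied to non-key positions of Cld copies and to
#: subfamily template copies (well under the 10% divergence at which distinct
#: templates stay separable).
POINT_MUTATION_RATE = 0.03

GENUS_VOCABULARY = (
    "Azospira",
    "Dechloromonas",
    "Ideonella",
    "Magnetospirillum",
    "Nitrobacter",
    "Nitrospina",
    "Nitrospira",
    "Planctomyces",
    "Pseudomonas",
    "Rubrivivax",
    "Sedimenticola",
    "Sulfurimonas",
)

PHYLUM_VOCABULARY = (
    "Proteobacteria",
    "Nitrospirae",
    "Planctomycetes",
    "Cyanobacteria",
    "Actinobacteria",
)


def _make_template() -> str:
    """Fixed Cld-like template with the four catalytic residues planted at the
    reference positions (K92, H114, R127, E167)."""
    rng = np.random.default_rng(20221006)
    seq = rng.choice(_AA, size=CLD_TEMPLATE_LENGTH)
    for pos, aa in DEFAULT_KEY_RESIDUES:
        seq[pos - 1] = aa
    return "".join(seq)


CLD_TEMPLATE = _make_template()
_KEY_POSITIONS_0 = np.array([pos - 1 for pos, _ in DEFAULT_KEY_RESIDUES])


@dataclass(frozen=True)
class AssociatedSubfamily:
    """A subfamily planted near anchors: present within ``max_offset`` ordinal
    positions of an anchor with probability ``probability``."""

    subfamily_id: str
    probability: float
    max_offset: int = 3


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_contigs: int = 20
    genes_per_contig: int = 40
    n_anchors: int = 10
    associated_subfamilies: tuple[AssociatedSubfamily, ...] = ()
    background_subfamilies: int = 50
    archetypes: tuple[tuple[str, ...], ...] = ()
    residue_mutation_rate: float = 0.0
    cross_genus_identical: bool = False

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise ConfigurationError(f"n_contigs must be >= 1, got {self.n_contigs}")
        if self.genes_per_contig < 1:
            raise ConfigurationError(
                f"genes_per_contig must be >= 1, got {self.genes_per_contig}"
            )
        if self.n_anchors < 0:
            raise ConfigurationError(f"n_anchors must be >= 0, got {self.n_anchors}")
        if self.n_anchors > self.n_contigs * self.genes_per_contig:
            raise ConfigurationError(
                f"n_anchors = {self.n_anchors} exceeds total genes "
                f"{self.n_contigs * self.genes_per_contig}"
            )
        if self.background_subfamilies < 1:
            raise ConfigurationError(
                f"background_subfamilies must be >= 1, got "
                f"{self.background_subfamilies}"
            )
        if not 0 <= self.residue_mutation_rate <= 1:
            raise ConfigurationError(
                f"residue_mutation_rate must be in [0, 1], got "
                f"{self.residue_mutation_rate}"
            )
        for assoc in self.associated_subfamilies:
            if not 0 <= assoc.probability <= 1:
                raise ConfigurationError(
                    f"associated_subfamilies: probability for "
                    f"{assoc.subfamily_id!r} must be in [0, 1], got "
                    f"{assoc.probability}"
                )
            if not 1 <= assoc.max_offset <= 10:
                raise ConfigurationError(
                    f"associated_subfamilies: max_offset for "
                    f"{assoc.subfamily_id!r} must be in 1..10 (the neighborhood "
                    f"radius), got {assoc.max_offset}"
                )
        for repertoire in self.archetypes:
            if not repertoire:
                raise ConfigurationError("archetypes: empty subfamily repertoire")
        if self.cross_genus_identical and self.n_anchors < 2:
            raise ConfigurationError(
                "cross_genus_identical requires n_anchors >= 2"
            )


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth for scoring downstream stages."""

    anchor_gene_ids: tuple[str, ...]
    anchor_protein_ids: tuple[str, ...]
    subfamily_by_gene: dict[str, str]
    archetype_by_anchor: dict[str, str]
    key_residue_count_by_protein: dict[str, int]


@dataclass
class SyntheticDataset:
    config: SynthConfig
    genes: pd.DataFrame  # gene table incl. per-contig ordinal index
    proteins: dict[str, str]  # every gene's protein sequence
    alignment: dict[str, str]  # reference + anchor Cld proteins, equal length
    tree_newick: str
    truth: SynthTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts; byte-identical across runs with one config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / "genes.gff3",
            "gene_tsv": outdir / "genes.tsv",
            "proteins": outdir / "proteins.faa",
            "alignment": outdir / "cld_alignment.afa",
            "tree": outdir / "tree.nwk",
            "truth_anchors": outdir / "truth_anchors.tsv",
            "truth_subfamilies": outdir / "truth_subfamilies.tsv",
            "truth_residues": outdir / "truth_residues.tsv",
        }
        self._write_gff3(paths["gff3"])
        self.genes.to_csv(paths["gene_tsv"], sep="\t", index=False, lineterminator="\n")
        _write_fasta(self.proteins, paths["proteins"])
        _write_fasta(self.alignment, paths["alignment"])
        paths["tree"].write_text(self.tree_newick + "\n")
        with open(paths["truth_anchors"], "w") as handle:
            handle.write("anchor_gene_id\tanchor_protein_id\tarchetype\n")
            for gid, pid in zip(
                self.truth.anchor_gene_ids, self.truth.anchor_protein_ids
            ):
                handle.write(f"{gid}\t{pid}\t{self.truth.archetype_by_anchor[gid]}\n")
        with open(paths["truth_subfamilies"], "w") as handle:
            handle.write("gene_id\tsubfamily_id\n")
            for gid in self.genes["gene_id"]:
                handle.write(f"{gid}\t{self.truth.subfamily_by_gene[gid]}\n")
        with open(paths["truth_residues"], "w") as handle:
            handle.write("protein_id\tn_key_residues\n")
            for pid in sorted(self.truth.key_residue_count_by_protein):
                count = self.truth.key_residue_count_by_protein[pid]
                handle.write(f"{pid}\t{count}\n")
        return paths

    def _write_gff3(self, path: Path) -> None:
        with open(path, "w") as handle:
            handle.write("##gff-version 3\n")
            anchor_set = set(self.truth.anchor_gene_ids)
            for row in self.genes.itertuples(index=False):
                attrs = (
                    f"ID={row.gene_id};protein_id={row.protein_id};"
                    f"genome_id={row.genome_id};genus={row.genus};"
                    f"phylum={row.phylum};source_type={row.source};"
                    f"cld={'true' if row.gene_id in anchor_set else 'false'}"
                )
                handle.write(
                    f"{row.contig_id}\tcldkit_synth\tCDS\t{row.start}\t{row.end}\t"
                    f".\t{row.strand}\t0\t{attrs}\n"
                )


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def random_tree(leaf_labels: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating tree over the labels, Newick with branch lengths.

    Built by repeated random joins with exponential(0.1) branch lengths —
    coalescent-style in shape; only branch-length arithmetic matters to the
    clade partition, not evolutionary realism.
    """
    if not leaf_labels:
        raise ConfigurationError("random_tree requires at least one leaf")
    nodes = list(leaf_labels)
    if len(nodes) == 1:
        return f"({nodes[0]}:0.0);"
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bl_i, bl_j = rng.exponential(0.1, size=2)
        merged = f"({nodes[i]}:{bl_i:.6f},{nodes[j]}:{bl_j:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def _mutate(template_idx: np.ndarray, rate: float, rng: np.random.Generator,
            protect: np.ndarray | None = None) -> np.ndarray:
    """Point-substitute positions of an index-encoded sequence at ``rate``;
    substitutions always change the residue. ``protect`` positions are never
    touched."""
    out = template_idx.copy()
    mask = rng.random(len(out)) < rate
    if protect is not None:
        mask[protect] = False
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 20, size=n)) % 20
    return out


def _anchor_slots(config: SynthConfig) -> list[tuple[int, int]]:
    """(contig, ordinal index) slots for anchors with non-overlapping ±10
    windows, filled breadth-first across contigs."""
    window = 2 * 10 + 1
    per_contig = max(1, config.genes_per_contig // window)
    capacity = config.n_contigs * per_contig
    if config.n_anchors > capacity:
        raise ConfigurationError(
            f"n_anchors = {config.n_anchors} exceeds anchor capacity {capacity} "
            f"({per_contig} non-overlapping windows per contig); raise n_contigs "
            "or genes_per_contig"
        )
    slots = []
    for rank in range(per_contig):
        base = rank * window + min(10, config.genes_per_contig // 2)
        if base >= config.genes_per_contig:
            break
        for contig in range(config.n_contigs):
            slots.append((contig, base))
    return slots[: config.n_anchors]


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with known planted structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.genes_per_contig
    anchors = _anchor_slots(config)
    anchor_lookup = {slot: rank for rank, slot in enumerate(anchors)}

    # per-contig labels (one genome per contig)
    genus = [GENUS_VOCABULARY[int(g)] for g in
             rng.integers(0, len(GENUS_VOCABULARY), size=config.n_contigs)]
    phylum = [PHYLUM_VOCABULARY[int(p)] for p in
              rng.integers(0, len(PHYLUM_VOCABULARY), size=config.n_contigs)]
    if config.cross_genus_identical:
        genus[anchors[0][0]] = GENUS_VOCABULARY[0]
        genus[anchors[1][0]] = GENUS_VOCABULARY[1]

    strands = rng.choice(np.array(["+", "-"]), size=config.n_contigs * n_genes)

    # subfamily layout: background everywhere, then archetype fill in anchor
    # windows, then planted associated subfamilies, then the anchor itself
    sid_grid: dict[tuple[int, int], str] = {}
    bg_ids = [f"bg{i:03d}" for i in range(config.background_subfamilies)]
    bg_draw = rng.integers(0, len(bg_ids), size=config.n_contigs * n_genes)
    for contig in range(config.n_contigs):
        for idx in range(n_genes):
            sid_grid[(contig, idx)] = bg_ids[int(bg_draw[contig * n_genes + idx])]

    archetype_by_anchor: dict[int, str] = {}
    for rank, (contig, idx) in enumerate(anchors):
        if config.archetypes:
            # round-robin: archetype sizes are exact, not binomially noisy
            arch = rank % len(config.archetypes)
            archetype_by_anchor[rank] = f"arch{arch}"
            repertoire = config.archetypes[arch]
            for j in range(max(0, idx - 10), min(n_genes, idx + 11)):
                if j == idx:
                    continue
                sid_grid[(contig, j)] = repertoire[
                    int(rng.integers(0, len(repertoire)))
                ]
        else:
            archetype_by_anchor[rank] = "none"
        taken: set[int] = set()
        for assoc in config.associated_subfamilies:
            if rng.random() >= assoc.probability:
                continue
            choices = [
                o
                for o in range(-assoc.max_offset, assoc.max_offset + 1)
                if o != 0 and 0 <= idx + o < n_genes and idx + o not in taken
            ]
            if not choices:
                raise ConfigurationError(
                    f"associated_subfamilies: no free slot within "
                    f"±{assoc.max_offset} of anchor {rank}; raise genes_per_contig"
                )
            offset = choices[int(rng.integers(0, len(choices)))]
            taken.add(idx + offset)
            sid_grid[(contig, idx + offset)] = assoc.subfamily_id
        sid_grid[(contig, idx)] = "cld_1"

    # per-subfamily sequence templates (index-encoded), sorted for determinism
    used_sids = sorted(set(sid_grid.values()) - {"cld_1"})
    templates: dict[str, np.ndarray] = {}
    for sid in used_sids:
        length = int(rng.integers(150, 251))
        templates[sid] = rng.integers(0, 20, size=length)
    cld_template_idx = np.array([_AA_INDEX[a] for a in CLD_TEMPLATE])

    # sequences, gene table, truth
    rows = []
    proteins: dict[str, str] = {}
    key_counts: dict[str, int] = {}
    subfamily_by_gene: dict[str, str] = {}
    anchor_gene_ids: list[str] = [""] * len(anchors)
    anchor_protein_ids: list[str] = [""] * len(anchors)
    identical_pair_seq: str | None = None

    for contig in range(config.n_contigs):
        contig_id = f"ctg{contig:04d}"
        genome_id = f"G{contig:04d}"
        for idx in range(n_genes):
            gene_id = f"g{contig:04d}_{idx:03d}"
            protein_id = f"p{contig:04d}_{idx:03d}"
            sid = sid_grid[(contig, idx)]
            subfamily_by_gene[gene_id] = sid
            anchor_rank = anchor_lookup.get((contig, idx))
            if anchor_rank is not None:
                anchor_gene_ids[anchor_rank] = gene_id
                anchor_protein_ids[anchor_rank] = protein_id
                if (
                    config.cross_genus_identical
                    and anchor_rank == 1
                    and identical_pair_seq is not None
                ):
                    seq = identical_pair_seq
                    count = key_counts[anchor_protein_ids[0]]
                else:
                    seq_idx = _mutate(
                        cld_template_idx,
                        POINT_MUTATION_RATE,
                        rng,
                        protect=_KEY_POSITIONS_0,
                    )
                    count = 4
                    if rng.random() < config.residue_mutation_rate:
                        hit = _KEY_POSITIONS_0[int(rng.integers(0, 4))]
                        seq_idx[hit] = (seq_idx[hit] + int(rng.integers(1, 20))) % 20
                        count = 3
                    seq = "".join(_AA[seq_idx])
                    if config.cross_genus_identical and anchor_rank == 0:
                        identical_pair_seq = seq
                key_counts[protein_id] = count
            else:
                seq_idx = _mutate(templates[sid], POINT_MUTATION_RATE, rng)
                seq = "".join(_AA[seq_idx])
            proteins[protein_id] = seq
            start = idx * 1000 + 1
            rows.append(
                {
                    "gene_id": gene_id,
                    "protein_id": protein_id,
                    "contig_id": contig_id,
                    "genome_id": genome_id,
                    "start": start,
                    "end": start + 3 * len(seq) + 2,
                    "strand": str(strands[contig * n_genes + idx]),
                    "genus": genus[contig],
                    "phylum": phylum[contig],
                    "source": "genomic",
                }
            )

    genes = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    genes["index"] = genes.groupby("contig_id", sort=False).cumcount()

    alignment = {REFERENCE_ID: CLD_TEMPLATE}
    for pid in anchor_protein_ids:
        alignment[pid] = proteins[pid]
    key_counts[REFERENCE_ID] = 4

    tree = (
        random_tree(list(anchor_protein_ids), rng)
        if anchor_protein_ids
        else "();"
    )

    truth = SynthTruth(
        anchor_gene_ids=tuple(anchor_gene_ids),
        anchor_protein_ids=tuple(anchor_protein_ids),
        subfamily_by_gene=subfamily_by_gene,
        archetype_by_anchor={
            gid: archetype_by_anchor[rank]
            for rank, gid in enumerate(anchor_gene_ids)
        },
        key_residue_count_by_protein=key_counts,
    )
    return SyntheticDataset(
        config=config,
        genes=genes,
        proteins=proteins,
        alignment=alignment,
        tree_newick=tree,
        truth=truth,
    )
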