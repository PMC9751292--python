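"""End-to-end pipeline orchestration with provenance capture.

Stages run in dependency order: identify → neighborhoods → subfamilies →
linkage → groups, with clade partitioning, reductase screening and frequency
metrics as independent stages that run whenever their inputs are configured.
Every run writes a manifest recording parameters, input checksums and output
files; deterministic stages reproduce byte-identical outputs under one config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clades import partition_by_mean_distance, summarize_clades
from .errors import CldkitError, ConfigurationError
from .frequency import environment_table
from .groups import embed_and_group, presence_matrix
from .identify import (
    KeyResidueSpec,
    call_proteins,
    map_reference_residues,
    read_alignment,
    read_signal_peptides,
)
from .linkage import build_network, rank_linkage, write_edge_list
from .neighborhoods import (
    extract_neighborhoods,
    neighborhoods_to_frame,
    read_gene_table,
)
from .subfamilies import (
    force_cld_subfamilies,
    greedy_cluster,
    import_cluster_tsv,
    read_fasta,
    write_cluster_tsv,
)
from .screen import classify_genomes, parse_hmm_table

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    Input paths left as ``None`` disable the stages that need them. Every
    parameter that the underlying study left unstated surfaces here with its
    default (``min_samples``, ``evalue_cutoff``, greedy-clustering thresholds,
    the clade threshold itself) so a run records exactly what was assumed.
    """

    output_dir: str = "cldkit_run"

    # inputs
    alignment: str | None = None
    reference_id: str | None = None
    signal_peptides: str | None = None
    gene_table: str | None = None
    gene_table_format: str = "gff3"
    anchors: str | None = None  # one anchor gene id per line; else derived
    proteins: str | None = None
    import_clusters: str | None = None
    tree: str | None = None
    hmm_table: str | None = None
    hmm_dialect: str = "tblout"
    environment_counts: str | None = None

    # stage parameters
    radius: int = 10
    clade_threshold: float = 0.5
    min_identity: float = 0.5
    min_coverage: float = 0.5
    kmer: int = 5
    hit_threshold: float = 0.1
    min_genes: int = 10
    seed: int = 17
    reduce_dims: int = 50
    perplexity: float = 50.0
    iterations: int = 5000
    distance: float = 4.0
    min_samples: int = 5
    evalue_cutoff: float = 1e-5
    genes_per_genome: int = 5000
    run_groups: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def input_paths(self) -> dict[str, str]:
        fields = (
            "alignment",
            "signal_peptides",
            "gene_table",
            "anchors",
            "proteins",
            "import_clusters",
            "tree",
            "hmm_table",
            "environment_counts",
        )
        return {
            name: value
            for name in fields
            if (value := getattr(self, name)) is not None
        }

    def validate(self) -> None:
        for name, path in self.input_paths().items():
            if not Path(path).exists():
                raise ConfigurationError(f"{name}: input path {path!r} does not exist")
        if self.alignment is not None and self.reference_id is None:
            raise ConfigurationError(
                "reference_id is required when an alignment is given"
            )


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


@dataclass
class _Manifest:
    config: dict
    inputs: dict[str, dict] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, dict] = field(default_factory=dict)
    failed_stage: str | None = None

    def record_output(self, stage: str, path: Path) -> None:
        self.outputs[path.name] = {
            "stage": stage,
            "path": str(path),
            "sha256": _sha256(path),
        }


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest (also written as
    ``manifest.json`` in the output directory).

    A stage failure raises :class:`CldkitError` naming the stage; outputs of
    completed stages are retained and the manifest is still written, with a
    failure marker.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config={k: getattr(config, k) for k in config.__dataclass_fields__})
    for name, path in config.input_paths().items():
        manifest.inputs[name] = {"path": path, "sha256": _sha256(path)}

    state: dict = {}
    try:
        _run_stages(config, outdir, manifest, state)
    except CldkitError as exc:
        manifest.failed_stage = manifest.stages[-1] if manifest.stages else "setup"
        _finish(manifest, outdir)
        raise CldkitError(
            f"stage {manifest.failed_stage!r} failed: {exc}"
        ) from exc
    return _finish(manifest, outdir)


def _finish(manifest: _Manifest, outdir: Path) -> dict:
    payload = {
        "cldkit_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": manifest.config,
        "inputs": manifest.inputs,
        "stages": manifest.stages,
        "outputs": manifest.outputs,
        "failed_stage": manifest.failed_stage,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return payload


def _run_stages(
    config: RunConfig, outdir: Path, manifest: _Manifest, state: dict
) -> None:
    calls = None
    if config.alignment is not None:
        manifest.stages.append("identify")
        alignment = read_alignment(config.alignment)
        spec = KeyResidueSpec(reference_id=config.reference_id)
        residue_map = map_reference_residues(alignment, spec)
        signal = (
            read_signal_peptides(config.signal_peptides)
            if config.signal_peptides
            else None
        )
        calls = call_proteins(alignment, residue_map, signal_peptides=signal)
        path = outdir / "cld_calls.tsv"
        _write_tsv(calls, path)
        manifest.record_output("identify", path)
        state["calls"] = calls
        state["alignment"] = alignment

    genes = None
    neighborhoods = None
    if config.gene_table is not None:
        manifest.stages.append("neighborhoods")
        genes = read_gene_table(config.gene_table, format=config.gene_table_format)
        if config.anchors is not None:
            anchor_ids = [
                line.strip()
                for line in Path(config.anchors).read_text().splitlines()
                if line.strip()
            ]
        elif calls is not None:
            cld_proteins = set(calls.loc[calls["is_cld"], "protein_id"])
            anchor_ids = list(
                genes.loc[genes["protein_id"].isin(cld_proteins), "gene_id"]
            )
        else:
            raise ConfigurationError(
                "anchors: provide an anchor id file or an alignment from which "
                "Cld anchors can be derived"
            )
        neighborhoods = extract_neighborhoods(genes, anchor_ids, radius=config.radius)
        path = outdir / "neighborhoods.tsv"
        _write_tsv(neighborhoods_to_frame(neighborhoods), path)
        manifest.record_output("neighborhoods", path)
        state["genes"] = genes
        state["neighborhoods"] = neighborhoods

    assignment = None
    if config.import_clusters is not None or config.proteins is not None:
        manifest.stages.append("subfamilies")
        if config.import_clusters is not None:
            assignment = import_cluster_tsv(config.import_clusters)
        else:
            assignment = greedy_cluster(
                read_fasta(config.proteins),
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
                kmer=config.kmer,
            )
        if calls is not None and genes is not None:
            cld_proteins = set(calls.loc[calls["is_cld"], "protein_id"])
            # single synthetic lineage unless a lineage map is imported
            lineages = {
                pid: 1
                for pid in genes["protein_id"]
                if pid in cld_proteins and pid in assignment.membership
            }
            if lineages:
                assignment = force_cld_subfamilies(assignment, lineages)
        path = outdir / "subfamilies.tsv"
        write_cluster_tsv(assignment, path)
        manifest.record_output("subfamilies", path)
        state["assignment"] = assignment

    if neighborhoods is not None and assignment is not None:
        manifest.stages.append("linkage")
        network = build_network(neighborhoods, assignment)
        table = rank_linkage(network, hit_threshold=config.hit_threshold)
        path = outdir / "linkage.tsv"
        _write_tsv(table, path)
        manifest.record_output("linkage", path)
        edges = outdir / "network_edges.tsv"
        write_edge_list(network, edges)
        manifest.record_output("linkage", edges)
        state["network"] = network
        state["linkage"] = table

        if config.run_groups:
            matrix = presence_matrix(
                neighborhoods, assignment, min_genes=config.min_genes
            )
            if len(matrix) > 3 * config.perplexity:
                manifest.stages.append("groups")
                result = embed_and_group(
                    matrix,
                    seed=config.seed,
                    reduce_dims=config.reduce_dims,
                    perplexity=config.perplexity,
                    iterations=config.iterations,
                    distance=config.distance,
                    min_samples=config.min_samples,
                )
                path = outdir / "neighborhood_groups.tsv"
                _write_tsv(result.to_frame(), path)
                manifest.record_output("groups", path)
                state["groups"] = result

    if config.tree is not None:
        manifest.stages.append("clades")
        partition = partition_by_mean_distance(config.tree, config.clade_threshold)
        path = outdir / "clades.tsv"
        _write_tsv(partition.to_frame(), path)
        manifest.record_output("clades", path)
        state["partition"] = partition
        if calls is not None and genes is not None:
            annotations = calls.set_index("protein_id").join(
                genes.set_index("protein_id")[["genus", "source"]]
            )
            annotations["sequence"] = pd.Series(state.get("alignment", {}))
            covered = set(annotations.index)
            if all(leaf in covered for leaf in partition.leaf_ids):
                summary = summarize_clades(partition, annotations)
                path = outdir / "clade_summaries.tsv"
                _write_tsv(summary, path)
                manifest.record_output("clades", path)

    if config.hmm_table is not None and genes is not None and calls is not None:
        manifest.stages.append("screen")
        protein_to_genome = dict(zip(genes["protein_id"], genes["genome_id"]))
        hits = parse_hmm_table(
            config.hmm_table,
            dialect=config.hmm_dialect,
            protein_to_genome=protein_to_genome,
        )
        cld_proteins = set(calls.loc[calls["is_cld"], "protein_id"])
        cld_by_genome = {
            genome: bool(set(grp["protein_id"]) & cld_proteins)
            for genome, grp in genes.groupby("genome_id")
        }
        screen = classify_genomes(cld_by_genome, hits, evalue_cutoff=config.evalue_cutoff)
        path = outdir / "genome_screen.tsv"
        _write_tsv(screen, path)
        manifest.record_output("screen", path)
        state["screen"] = screen

    if config.environment_counts is not None:
        manifest.stages.append("frequency")
        counts = pd.read_csv(config.environment_counts, sep="\t")
        freq = environment_table(counts, genes_per_genome=config.genes_per_genome)
        path = outdir / "environment_frequency.tsv"
        _write_tsv(freq, path)
        manifest.record_output("frequency", path)
        state["frequency"] = freq
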