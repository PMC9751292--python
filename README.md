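# cldkit

Comparative genomics of **chlorite dismutase (Cld)**, the heme enzyme that
detoxifies chlorite (ClO₂⁻) into chloride and O₂. Because chlorite sits at an
intermediate oxidation state of chlorine, *cld* is a specific genomic
biomarker for oxidized chlorine species: any genome carrying an active Cld has
met chlorite, and the genes recurrently co-located with *cld* are candidates
for chlorine redox biology. `cldkit` is a toolkit for microbial genomics
researchers who want to run this biomarker-anchored analysis on their own
sequence collections — or benchmark it on synthetic data with planted truth.

## What it computes

- **Cld identification.** Within the Cld/HemQ protein family, active Cld is
  defined by four catalytic residues — the distal heme arginine plus the
  proximal lysine, histidine and glutamate (R127, K92, H114, E167 in the
  *Nitrobacter winogradskyi* Nb-255 reference numbering). Reference positions
  are mapped onto alignment columns by gap-aware arithmetic; a protein is Cld
  iff all four columns carry the expected residue. N-/C-terminal extensions
  beyond the average Cld span (flagged above 20 aa) and externally predicted
  signal peptides are recorded per protein.
- **Clade partitioning.** A rooted Cld phylogeny is cut into disjoint clades
  at nodes whose mean node-to-leaf path length is within a branch-length
  threshold, then summarized per clade (key-residue fractions, genus counts,
  and identical sequences shared across genera — the footprint of recent
  horizontal transfer).
- **Genomic neighborhoods.** The anchor *cld* gene ±10 genes on the same
  contig, from GFF3 or TSV gene tables.
- **Subfamilies and linkage.** Neighborhood proteins are clustered into
  subfamilies (imported from an external clustering tool, or natively by
  deterministic greedy k-mer containment). Subfamilies become nodes of a
  co-occurrence network with an edge whenever two subfamilies share a
  neighborhood. The linkage statistic for subfamily *i* is the local
  clustering coefficient

  *C(i) = e(i) / [k(i)·(k(i)−1)/2]*,

  where *k(i)* is its number of network neighbors and *e(i)* the edges among
  them, computed in exact rational arithmetic. **Low** *C* means the
  subfamily recurs across many different neighborhood types — genetic linkage
  to *cld* rather than chance co-location; subfamilies with *C* < 0.1 are
  flagged as hits.
- **Neighborhood grouping.** Neighborhoods with ≥10 genes, encoded as a
  binary subfamily presence/absence matrix, are reduced by PCA (50
  components), embedded with t-SNE (perplexity 50, 5000 iterations) and
  grouped by DBSCAN (radius 4) — exposed as a scikit-learn-style estimator
  (`NeighborhoodGrouper`).
- **Reductase screen.** Genomes encoding Cld but no DMSO-reductase-family
  enzyme capable of (per)chlorate reduction (from HMMER tblout/domtblout
  searches) are classified as non-(per)chlorate reducers — their chlorite
  must come from some other source, such as oxidative chemistry.
- **Frequency metrics.** *cld* per million genes per environment, and its
  conversion to an estimated percent of genomes (at 5000 genes per genome,
  1 *cld* per million genes ≈ 0.5% of genomes).

A synthetic-data module generates contigs, proteins, alignments and trees
with planted anchors, associated subfamilies, neighborhood archetypes and
key-residue knockouts, so every stage is testable against known truth.

## Worked example

Sixty synthetic *cld* anchors are planted on 60 contigs, a subfamily
`rcs_like` is placed within ±3 genes of each anchor with probability 0.9, two
neighborhood archetypes fill the windows, and 10% of anchors lose one key
residue:

```python
from cldkit import (
    KeyResidueSpec, SynthConfig, generate_dataset,
    map_reference_residues, extract_neighborhoods,
    build_network, rank_linkage, greedy_cluster,
)
from cldkit.identify import call_proteins
from cldkit.subfamilies import force_cld_subfamilies
from cldkit.synthetic import REFERENCE_ID, AssociatedSubfamily

config = SynthConfig(
    seed=11, n_contigs=60, genes_per_contig=21, n_anchors=60,
    associated_subfamilies=(AssociatedSubfamily("rcs_like", 0.9, 3),),
    archetypes=(tuple(f"A{i}" for i in range(8)), tuple(f"B{i}" for i in range(8))),
    background_subfamilies=10, residue_mutation_rate=0.1,
)
data = generate_dataset(config)

residue_map = map_reference_residues(
    data.alignment, KeyResidueSpec(reference_id=REFERENCE_ID))
calls = call_proteins(data.alignment, residue_map).set_index("protein_id")
cld = set(calls.index[calls["is_cld"]]) - {REFERENCE_ID}
print(f"Cld calls: {len(cld)} of {config.n_anchors} planted anchors")

anchors = data.genes.set_index("protein_id").loc[sorted(cld), "gene_id"]
neighborhoods = extract_neighborhoods(data.genes, anchors)
assignment = force_cld_subfamilies(greedy_cluster(data.proteins), {p: 1 for p in cld})
network = build_network(neighborhoods, assignment)
print(rank_linkage(network, hit_threshold=0.1).head(4).to_string(index=False))
```

prints:

```
Cld calls: 50 of 60 planted anchors
subfamily_id  clustering_coefficient  occurrence   hit
       cld_1                   0.529          50 False
   p0000_013                   0.529          47 False
   p0000_000                   1.000          23 False
   p0000_001                   1.000          22 False
```

Fifty of the 60 anchors kept all four key residues (the rest were knocked
out), and each yields one neighborhood. The table ranks subfamilies by
clustering coefficient, lowest first: `cld_1` is the anchor itself, and
`p0000_013` is the cluster holding the planted `rcs_like` subfamily — it
spans both archetypes, so its neighbors in the network are rarely connected
to each other and its coefficient (0.529) falls well below the
archetype-exclusive subfamilies (1.0). On real data, hits are the rows with
coefficient < 0.1; here the network is far too small for any coefficient to
reach that regime, which is why the `hit` column is false throughout.

The same stages are available as a CLI:

```sh
cldkit simulate --seed 11 --n-contigs 60 --genes-per-contig 21 --n-anchors 60 \
    --associated rcs_like:0.9:3 --outdir data/
cldkit identify --alignment data/cld_alignment.afa --reference Nwinogradskyi_Nb255_Cld
cldkit run --config run.yaml     # all stages + provenance manifest
```

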