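# Methods

This note records the models and procedures `cldkit` implements, the
parameters that matter, the numerical conventions adopted where a choice had
to be made, and what the synthetic benchmarks do and do not demonstrate.

## Cld identification by key residues

Chlorite dismutase shares a protein family with non-Cld relatives (largely
heme-biosynthesis decarboxylases), and public annotations of "Cld-like"
proteins are unreliable, so activity is inferred structurally: a protein is
called Cld iff it carries all four catalytic residues — the distal heme
arginine and proximal lysine, histidine and glutamate, at positions 127, 92,
114 and 167 of the *Nitrobacter winogradskyi* Nb-255 reference. Family
membership is a precondition of the input alignment and is not re-checked.

Conventions:

- Reference positions are resolved to alignment columns by gap-stripping
  arithmetic: column *k* maps to ungapped position *p* when the reference row
  holds exactly *p* residues up to and including column *k*. The reference
  residue at each mapped column is verified against the expected amino acid;
  a mismatch is an error, not a silent miscount.
- Residue matching is exact and case-insensitive. Conservative substitutions
  do not count: the calls are discrete "key residues present", and any looser
  rule would need biochemical justification the analysis does not have. Gaps
  and ambiguity codes (X, B, Z) never match.
- Proteins truncated over a key column (common in metagenome-derived
  fragments) are ambiguous between "residue absent" and "sequence missing".
  Counts treat gaps as non-matches, but the per-protein gap count at key
  columns is reported separately (`n_gap_key_columns`) so either convention
  can be applied downstream.
- Terminal extensions are measured against the *mean* first- and
  last-occupied alignment columns over the called Cld set, each mean rounded
  half away from zero to an integer column (no rounding rule is inherent to
  the definition; a fixed one keeps outputs reproducible). A protein's
  N-terminal extension counts its residues strictly before the mean start;
  C-terminal strictly after the mean end; either side >20 aa sets
  `long_extension_flag`.
- Signal peptides are ingested from an external predictor's verdicts as a
  two-column TSV; the toolkit never predicts them itself.

## Clade partitioning

A rooted tree with branch lengths is cut by pre-order traversal: a node whose
mean path length to its descendant leaves is ≤ the threshold is emitted as a
clade and its subtree skipped; leaves reached with no qualifying ancestor
become singletons. This yields, by construction, a disjoint cover of the leaf
set in which every emitted node is maximal (its parent's mean exceeds the
threshold).

- The comparison is ≤ by default; a strict `<` variant is available
  (`inclusive=False`) since the two differ only at exact equality, which has
  measure zero on real branch lengths.
- Multifurcations and zero-length branches are accepted. Trees explicitly
  marked unrooted and trees missing branch lengths are rejected; the rooting
  choice itself belongs to the caller.
- Clade ids follow pre-order discovery rank starting at 1. The threshold is a
  free parameter: published clade counts depend on a specific tree and
  threshold, and the partitioner makes no claim to reproduce any particular
  numbering.
- Clade summaries report counts by source (genomic/metagenomic), key-residue
  and signal-peptide fractions, length statistics (min, Q1, mean, Q3, max),
  genus counts, and `cross_genus_identical` — true when two members share an
  identical full sequence under different genus labels, the strongest
  available signature of very recent horizontal transfer.

## Neighborhoods

Genes are ordered within each contig by (start, end, gene id) and indexed
0…n−1; a neighborhood is the anchor gene ±10 ordinal positions (radius
configurable), truncated at contig ends, so 1–21 genes. Offsets are
strand-agnostic contig positions: no reorientation by anchor strand is
applied, because no such rule is defined for the analysis. Two nearby anchors
produce two overlapping neighborhoods; only neighborhoods with *identical*
member sets are deduplicated (first anchor kept), which is how anchor counts
can exceed neighborhood counts.

## Subfamilies

Two interchangeable routes produce the protein → subfamily map:

1. **Import** of standard two-column representative/member cluster output
   from an external alignment-based tool. This is the authoritative route
   when reproducing published subfamily structure; the files are treated as
   opaque ground truth.
2. **Native greedy clustering**, a deterministic approximation for
   benchmarks: proteins in decreasing length order (ties by id) join the
   first representative whose k-mer (k=5) containment — shared k-mers over
   the smaller k-mer set — is ≥0.5, provided the implied matched length
   covers ≥0.5 of both sequences; otherwise they found a new subfamily. The
   criterion is k-mer containment, not alignment statistics; at the planted
   divergence used in the benchmarks (~3% point mutations within a
   subfamily, unrelated templates between subfamilies) it recovers the true
   partition essentially perfectly, but it is not a substitute for
   alignment-based clustering on real, deeply diverged families.

When Cld calls are available, Cld proteins are pinned to fixed subfamily ids
(`cld_1`, `cld_2` by lineage) so linkage tables list the anchor under a
stable name regardless of how the generic clusterer grouped it.

## Co-occurrence network and the linkage statistic

One node per subfamily occurring in ≥1 neighborhood; an undirected edge joins
two subfamilies found together in ≥1 neighborhood (a configurable minimum
co-occurrence count defaults to 1 — no minimum is part of the method).
Repeats of a subfamily within one neighborhood contribute no self-loop, and a
node's `occurrence` counts neighborhoods, not genes.

The linkage statistic is the local clustering coefficient
*C(i) = e(i)/C(k(i),2)*, with *C(i)=0* for degree <2 (the common library
convention). A subfamily found in many *different* kinds of neighborhoods has
neighbors that rarely interconnect, hence low *C* — the signature of genetic
linkage to the anchor rather than chance co-location. Subfamilies are ranked
ascending (ties by id); hits are *C* strictly < 0.1. Coefficients are
computed with exact `Fraction` arithmetic and rounded to 3 decimals only on
output, so the hit boundary is judged exactly (a coefficient of exactly 1/10
is not a hit) rather than through floating-point representations of 0.1.

## Neighborhood grouping

Neighborhoods with ≥10 genes are encoded as a binary subfamily
presence/absence matrix (anchor subfamily columns included — nothing excludes
them). The matrix is reduced by PCA to 50 components (clipped to matrix
rank), embedded to 2-D by t-SNE with perplexity 50 and 5000 iterations, and
grouped by DBSCAN with radius 4 in embedding units. `min_samples` for DBSCAN
defaults to 5 (a standard default; it has no published value) and is recorded
in the output parameters. Fitting requires >3×perplexity rows for the
embedding to be well posed.

t-SNE is stochastic: one seed reproduces one embedding exactly, but group
*numbering* across seeds is arbitrary and the embedding scale depends on the
data, so evaluation uses permutation-invariant scores (adjusted Rand index)
and the package never claims to reproduce any particular published group
count. Points DBSCAN cannot assign are kept as a single catch-all
pseudo-group (label −1) rather than dropped, mirroring how diffuse
neighborhoods are reported alongside crisp groups.

## Reductase screen

Profile-HMM searches for DMSO-reductase-family enzymes are run externally;
the toolkit parses HMMER `tblout`/`domtblout` text output (full-sequence
E-value and bit score) and maps targets to genomes via a supplied protein →
genome table. A genome with Cld and no hit at E ≤ 1e-5 (cutoff configurable
and recorded — the screen's hit criteria are an assumption of this
implementation, not a published threshold) is classified
`non_perchlorate_reducer`; with a passing hit, `potential_reducer`; without
Cld, `no_cld`. The classification is a pure function of (has Cld, any
passing hit), and raising the cutoff can only move genomes toward
`potential_reducer`.

## Frequency metrics

Per environment: `cld_per_million = n_cld / n_genes × 10⁶` and
`est_percent_genomes = rate × genes_per_genome / 10⁶ × 100` with 5000 genes
per genome by default, so 1 *cld* per million genes ≈ 0.5% of genomes.
Environments are flagged `included` only above a strict >10⁷ sampled genes.

## Synthetic data: what it emulates, and what passing tests show

The generator plants exactly the structure the stages are meant to recover:

- contigs of ordered genes, one genome per contig, anchors spaced so ±10
  windows never overlap;
- associated subfamilies placed within a configured offset of each anchor
  with a configured probability (verified to match binomial expectation);
- archetypes — disjoint subfamily repertoires filling anchor windows,
  assigned round-robin so archetype sizes are exact;
- protein sequences as per-subfamily random templates (150–250 aa) copied
  with 3% point substitutions; anchor proteins copy a fixed 250-aa Cld-like
  template whose key residue columns are controlled exactly, with a
  configured probability of losing one key residue;
- genus labels from a fixed vocabulary, optionally duplicating one anchor
  sequence verbatim under two genera;
- a random bifurcating tree over anchor proteins with exponential(0.1)
  branch lengths.

All randomness flows from a single seed and outputs are byte-identical across
runs. The emulation is deliberately minimal: substitution-only evolution, no
indels (so family alignments are trivially ungapped), no gene gain/loss on
contigs, uniform template divergence, no database contamination or
fragmentary proteins. Passing benchmarks therefore demonstrate the
*correctness of the statistics and plumbing* — that low clustering
coefficients flag subfamilies spanning neighborhood types, that grouping
recovers content archetypes, that residue counting matches planted truth —
not robustness to alignment error, clustering ambiguity or annotation noise
in real data.

## Benchmark scales

The packaged benchmarks use 120–400 anchors (one neighborhood window per
contig), 500-protein alignments for the knockout-rate sweep, 500–1000 random
trees (≤40 leaves) and 200–500 random graphs (≤30 nodes) for oracle
equivalence — sizes at which every suite runs in well under a minute per
stage while leaving the planted effects unambiguous. The acceptance script
reports each quantity together with the problem size it was measured at.
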