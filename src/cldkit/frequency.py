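"""Biomarker frequency metrics across environments.

Metagenome surveys report, per environment, a total gene count and the number
of *cld* genes among them. Frequency is expressed as cld genes per million
genes; assuming an average bacterial genome of 5000 genes, a rate of 1 per
million corresponds to roughly 0.5% of genomes in the habitat encoding Cld.
Environments sampled with 10 million genes or fewer are marked as excluded
(too small for a stable rate) but still reported.
"""

from __future__ import annotations

import pandas as pd

from .errors import ParameterError

__all__ = [
    "GENES_PER_GENOME",
    "MIN_SAMPLE_GENES",
    "cld_per_million",
    "percent_genomes",
    "environment_table",
]

#: Assumed average number of genes per bacterial genome.
GENES_PER_GENOME = 5000

#: Environments must exceed this many sampled genes to be flagged as included.
MIN_SAMPLE_GENES = 10_000_000


def cld_per_million(n_cld: int, n_genes: int) -> float:
    """Rate of cld genes per million genes: ``n_cld / n_genes * 1e6``."""
    if n_genes <= 0:
        raise ZeroDivisionError(
            f"n_genes must be positive to form a rate, got {n_genes}"
        )
    if n_cld < 0:
        raise ParameterError(f"n_cld must be >= 0, got {n_cld}")
    return n_cld / n_genes * 1e6


def percent_genomes(rate: float, genes_per_genome: int = GENES_PER_GENOME) -> float:
    """Convert a per-million-genes rate to an estimated percent of genomes.

    ``rate * genes_per_genome / 1e6 * 100``: at 5000 genes per genome, 1 cld
    per million genes means about 0.5% of genomes encode Cld.
    """
    if genes_per_genome <= 0:
        raise ParameterError(
            f"genes_per_genome must be positive, got {genes_per_genome}"
        )
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    return rate * genes_per_genome / 1e6 * 100


def environment_table(
    counts: pd.DataFrame, genes_per_genome: int = GENES_PER_GENOME
) -> pd.DataFrame:
    """Per-environment frequency table.

    ``counts`` needs columns ``environment``, ``n_genes``, ``n_cld``. Adds
    ``cld_per_million``, ``est_percent_genomes`` and ``included`` (strictly
    more than 10 million sampled genes). Rows are sorted by descending rate.
    """
    required = {"environment", "n_genes", "n_cld"}
    missing = required - set(counts.columns)
    if missing:
        raise ParameterError(f"counts table lacks columns {sorted(missing)}")
    out = counts.copy()
    out["cld_per_million"] = [
        cld_per_million(int(c), int(g)) for c, g in zip(out["n_cld"], out["n_genes"])
    ]
    out["est_percent_genomes"] = [
        percent_genomes(r, genes_per_genome) for r in out["cld_per_million"]
    ]
    out["included"] = out["n_genes"] > MIN_SAMPLE_GENES
    return out.sort_values(
        ["cld_per_million", "environment"], ascending=[False, True]
    ).reset_index(drop=True)
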