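"""Gene tables and extraction of genomic neighborhoods around anchor genes.

A genomic neighborhood is the anchor gene (here, *cld*) plus up to 10 genes on
each side of it on the same contig — the unit over which gene co-occurrence is
scored. Gene tables come in as GFF3 (CDS features) or as a header-bearing TSV;
genes get 0-based ordinal indices along each contig and neighborhoods are
windows in index space, truncated at contig ends.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import MissingIdError, ParameterError, ParseError

__all__ = [
    "GENE_TABLE_COLUMNS",
    "Neighborhood",
    "read_gene_table",
    "write_gene_table_tsv",
    "extract_neighborhoods",
    "neighborhoods_to_frame",
    "neighborhoods_from_frame",
]

GENE_TABLE_COLUMNS = [
    "gene_id",
    "protein_id",
    "contig_id",
    "genome_id",
    "start",
    "end",
    "strand",
    "genus",
    "phylum",
    "source",
]

DEFAULT_RADIUS = 10


@dataclass(frozen=True)
class Neighborhood:
    """An anchor gene plus its flanking genes on one contig.

    ``offsets``, ``gene_ids`` and ``protein_ids`` are parallel tuples ordered
    by offset; offset 0 is the anchor.
    """

    neighborhood_id: str
    anchor_gene_id: str
    contig_id: str
    genome_id: str
    offsets: tuple[int, ...]
    gene_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if 0 not in self.offsets:
            raise ValueError("neighborhood must contain its anchor at offset 0")
        if list(self.offsets) != sorted(self.offsets):
            raise ValueError("offsets must be strictly increasing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    """Sort within contigs by (start, end, gene_id) and assign ordinal indices."""
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ParseError(f"duplicate gene_id values: {list(dupes[:5])}")
    df = df.sort_values(
        ["contig_id", "start", "end", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    df["index"] = df.groupby("contig_id", sort=False).cumcount()
    return df


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key] = urllib.parse.unquote(value)
    return attrs


def _read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated GFF3 columns, got {len(fields)}",
                    line=lineno,
                )
            seqid, _, ftype, start, end, _, strand, _, attr_field = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start!r}..{end!r}", line=lineno
                ) from None
            if start_i > end_i:
                raise ParseError(f"start {start_i} > end {end_i}", line=lineno)
            if strand not in "+-":
                raise ParseError(f"strand must be + or -, got {strand!r}", line=lineno)
            attrs = _parse_gff3_attributes(attr_field)
            gene_id = attrs.get("ID")
            if not gene_id:
                raise ParseError("CDS feature lacks an ID attribute", line=lineno)
            rows.append(
                {
                    "gene_id": gene_id,
                    "protein_id": attrs.get("protein_id", gene_id),
                    "contig_id": seqid,
                    "genome_id": attrs.get("genome_id", seqid),
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "genus": attrs.get("genus", ""),
                    "phylum": attrs.get("phylum", ""),
                    "source": attrs.get("source_type", "genomic"),
                }
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        # keep_default_na: empty genus/phylum cells stay "" rather than NaN
        df = pd.read_csv(
            path, sep="\t", dtype={"start": int, "end": int}, keep_default_na=False
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"malformed gene table TSV {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"gene table TSV {path} lacks columns {missing}")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0]
        raise ParseError(f"start > end for gene {df.loc[bad, 'gene_id']!r}")
    return df[GENE_TABLE_COLUMNS]


def read_gene_table(path: str | Path, format: str = "gff3") -> pd.DataFrame:
    """Read a gene table and assign per-contig ordinal indices.

    GFF3 input keeps CDS features only; coordinates are 1-based inclusive.
    Records are sorted within each contig by (start, end, gene_id) and indexed
    0..n-1 in the ``index`` column.
    """
    if format == "gff3":
        df = _read_gff3(path)
    elif format == "tsv":
        df = _read_tsv(path)
    else:
        raise ParameterError(f"unknown gene table format {format!r}")
    if df.empty:
        df = pd.DataFrame(columns=GENE_TABLE_COLUMNS)
        df["index"] = pd.Series(dtype=int)
        return df
    return _finalize(df)


def write_gene_table_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False, lineterminator="\n")


def extract_neighborhoods(
    genes: pd.DataFrame,
    anchor_gene_ids,
    radius: int = DEFAULT_RADIUS,
) -> list[Neighborhood]:
    """One neighborhood per anchor: genes within ``radius`` ordinal positions
    on the anchor's contig, truncated at contig boundaries.

    Offsets are strand-agnostic contig positions (no reorientation by anchor
    strand). Neighborhoods with identical member gene sets are deduplicated,
    keeping the first anchor in input order.
    """
    if radius < 0:
        raise ParameterError(f"radius must be >= 0, got {radius}")
    if "index" not in genes.columns:
        genes = _finalize(genes.copy())
    by_id = genes.set_index("gene_id", drop=False)
    by_contig = {cid: grp.sort_values("index") for cid, grp in genes.groupby("contig_id")}

    neighborhoods: list[Neighborhood] = []
    seen_member_sets: set[frozenset[str]] = set()
    for i, anchor_id in enumerate(anchor_gene_ids):
        if anchor_id not in by_id.index:
            raise MissingIdError(f"anchor gene {anchor_id!r} not in gene table")
        anchor = by_id.loc[anchor_id]
        contig = by_contig[anchor["contig_id"]]
        idx = int(anchor["index"])
        window = contig[(contig["index"] >= idx - radius) & (contig["index"] <= idx + radius)]
        members = frozenset(window["gene_id"])
        if members in seen_member_sets:
            continue
        seen_member_sets.add(members)
        neighborhoods.append(
            Neighborhood(
                neighborhood_id=f"nbh{len(neighborhoods):05d}",
                anchor_gene_id=anchor_id,
                contig_id=str(anchor["contig_id"]),
                genome_id=str(anchor["genome_id"]),
                offsets=tuple(int(j) - idx for j in window["index"]),
                gene_ids=tuple(window["gene_id"]),
                protein_ids=tuple(window["protein_id"]),
            )
        )
    return neighborhoods


def neighborhoods_to_frame(neighborhoods: list[Neighborhood]) -> pd.DataFrame:
    """Long-form table: one row per (neighborhood, member gene)."""
    rows = []
    for nbh in neighborhoods:
        for offset, gid, pid in zip(nbh.offsets, nbh.gene_ids, nbh.protein_ids):
            rows.append(
                {
                    "neighborhood_id": nbh.neighborhood_id,
                    "anchor_gene_id": nbh.anchor_gene_id,
                    "contig_id": nbh.contig_id,
                    "genome_id": nbh.genome_id,
                    "offset": offset,
                    "gene_id": gid,
                    "protein_id": pid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "neighborhood_id",
            "anchor_gene_id",
            "contig_id",
            "genome_id",
            "offset",
            "gene_id",
            "protein_id",
        ],
    )


def neighborhoods_from_frame(df: pd.DataFrame) -> list[Neighborhood]:
    """Inverse of :func:`neighborhoods_to_frame` (exact round-trip)."""
    out = []
    for nid, grp in df.groupby("neighborhood_id", sort=False):
        grp = grp.sort_values("offset")
        out.append(
            Neighborhood(
                neighborhood_id=str(nid),
                anchor_gene_id=str(grp["anchor_gene_id"].iloc[0]),
                contig_id=str(grp["contig_id"].iloc[0]),
                genome_id=str(grp["genome_id"].iloc[0]),
                offsets=tuple(int(o) for o in grp["offset"]),
                gene_ids=tuple(grp["gene_id"]),
                protein_ids=tuple(grp["protein_id"]),
            )
        )
    return out
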