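"""Identification of chlorite dismutase (Cld) by catalytic key residues.

Chlorite dismutase is a heme enzyme that cleaves chlorite into chloride and
molecular oxygen. Within its protein family, active Cld is distinguished from
non-Cld relatives (mostly heme-biosynthesis decarboxylases) by four catalytic
residues: the distal heme arginine and the proximal heme lysine, histidine and
glutamate. Given a family alignment containing a reference sequence with known
residue numbering, this module maps those reference positions onto alignment
columns, counts intact key residues per protein, classifies proteins as Cld
(all four residues present), and measures N-/C-terminal extensions relative to
the average Cld span in the alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, MissingIdError, ParseError, ResidueSpecError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = frozenset("-.")

#: Catalytic positions of the reference chlorite dismutase
#: (Nitrobacter winogradskyi Nb-255 numbering): proximal lysine K92,
#: proximal histidine H114, distal arginine R127, proximal glutamate E167.
DEFAULT_KEY_RESIDUES: tuple[tuple[int, str], ...] = (
    (92, "K"),
    (114, "H"),
    (127, "R"),
    (167, "E"),
)

#: Extensions longer than this many residues are flagged as unusually long.
LONG_EXTENSION_AA = 20


@dataclass(frozen=True)
class KeyResidueSpec:
    """Key residues on an ungapped reference sequence.

    Attributes
    ----------
    reference_id : str
        Identifier of the reference sequence in the alignment.
    residues : tuple of (int, str)
        (1-based ungapped reference position, expected single-letter amino
        acid), in strictly increasing position order.
    """

    reference_id: str
    residues: tuple[tuple[int, str], ...] = DEFAULT_KEY_RESIDUES

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.residues]
        if not positions:
            raise ResidueSpecError("residue spec is empty")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ResidueSpecError(
                f"spec positions must be strictly increasing, got {positions}"
            )
        if any(p < 1 for p in positions):
            raise ResidueSpecError(f"spec positions must be >= 1, got {positions}")
        for pos, aa in self.residues:
            if aa.upper() not in AMINO_ACIDS:
                raise ResidueSpecError(
                    f"expected amino acid at position {pos} must be one of the 20 "
                    f"standard letters, got {aa!r}"
                )


@dataclass(frozen=True)
class ResidueMap:
    """Key-residue reference positions resolved to alignment columns.

    ``entries`` holds (reference position, expected amino acid, 1-based
    alignment column), in increasing column order.
    """

    reference_id: str
    entries: tuple[tuple[int, str, int], ...]

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(col for _, _, col in self.entries)


def read_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered {id: aligned sequence} map."""
    alignment: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in alignment:
            raise ParseError(f"duplicate sequence id {record.id!r} in {path}")
        alignment[record.id] = str(record.seq)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ParseError(
            f"sequences in {path} have unequal aligned lengths {sorted(lengths)}"
        )
    return alignment


def as_mapping(alignment) -> Mapping[str, str]:
    """Accept a dict or an iterable of Biopython SeqRecords as an alignment."""
    if isinstance(alignment, Mapping):
        return alignment
    return {rec.id: str(rec.seq) for rec in alignment}


def map_reference_residues(alignment, spec: KeyResidueSpec) -> ResidueMap:
    """Resolve key-residue reference positions to alignment columns.

    Column *k* maps to spec position *p* such that stripping gaps from the
    reference row up to and including column *k* yields exactly *p* residues.
    The reference amino acid at each mapped column is verified against the
    expected letter.
    """
    aln = as_mapping(alignment)
    if spec.reference_id not in aln:
        raise MissingIdError(f"reference {spec.reference_id!r} absent from alignment")
    row = aln[spec.reference_id]
    ungapped_len = sum(1 for c in row if c not in GAP_CHARS)

    wanted = {pos: aa for pos, aa in spec.residues}
    entries: list[tuple[int, str, int]] = []
    seen = 0
    for col0, char in enumerate(row):
        if char in GAP_CHARS:
            continue
        seen += 1
        if seen in wanted:
            expected = wanted[seen]
            if char.upper() != expected.upper():
                raise ResidueSpecError(
                    f"reference {spec.reference_id!r} has {char!r} at position "
                    f"{seen}, spec expects {expected!r}"
                )
            entries.append((seen, expected.upper(), col0 + 1))
    missing = [p for p in wanted if p > ungapped_len]
    if missing:
        raise ResidueSpecError(
            f"spec positions {missing} exceed ungapped reference length {ungapped_len}"
        )
    return ResidueMap(reference_id=spec.reference_id, entries=tuple(entries))


def key_residue_profile(
    protein_id: str, alignment, residue_map: ResidueMap
) -> list[str]:
    """Per-key-column status for one protein: 'match', 'mismatch' or 'gap'.

    Gaps are reported separately from mismatches so that truncated
    (e.g. metagenome-derived partial) proteins can be treated under either
    convention downstream.
    """
    aln = as_mapping(alignment)
    if protein_id not in aln:
        raise MissingIdError(f"protein {protein_id!r} absent from alignment")
    row = aln[protein_id]
    statuses = []
    for _, expected, col in residue_map.entries:
        char = row[col - 1] if col - 1 < len(row) else "-"
        if char in GAP_CHARS:
            statuses.append("gap")
        elif char.upper() == expected:
            statuses.append("match")
        else:
            statuses.append("mismatch")
    return statuses


def count_key_residues(protein_id: str, alignment, residue_map: ResidueMap) -> int:
    """Number of mapped key columns at which the protein carries the expected
    amino acid (exact, case-insensitive match; gaps and ambiguity codes never
    match)."""
    return key_residue_profile(protein_id, alignment, residue_map).count("match")


def classify_cld(count: int) -> bool:
    """A protein is called Cld iff all four key residues are intact.

    Family membership is a precondition of the input alignment and is not
    re-checked here.
    """
    if not 0 <= count <= 4:
        raise ValueError(f"key-residue count must be in 0..4, got {count}")
    return count == 4


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _occupied_span(row: str) -> tuple[int, int] | None:
    """First and last non-gap column (1-based) of an aligned row."""
    first = last = None
    for i, c in enumerate(row):
        if c not in GAP_CHARS:
            if first is None:
                first = i + 1
            last = i + 1
    if first is None:
        return None
    return first, last


def terminal_extensions(alignment, cld_ids: Iterable[str]) -> pd.DataFrame:
    """N-/C-terminal extensions of each Cld protein beyond the average span.

    The mean first-occupied and mean last-occupied alignment columns are
    computed over ``cld_ids`` (arithmetic mean, rounded half away from zero).
    A protein's N-terminal extension is the number of its residues in columns
    strictly before the mean start; the C-terminal extension counts residues
    strictly after the mean end. Extensions longer than 20 aa are flagged.

    Returns a DataFrame indexed by protein id with columns
    ``n_term_extension``, ``c_term_extension``, ``long_extension_flag``.
    """
    aln = as_mapping(alignment)
    ids = list(cld_ids)
    if not ids:
        raise EmptyInputError("terminal_extensions requires a non-empty Cld id set")
    spans = {}
    for pid in ids:
        if pid not in aln:
            raise MissingIdError(f"protein {pid!r} absent from alignment")
        span = _occupied_span(aln[pid])
        if span is None:
            raise EmptyInputError(f"protein {pid!r} is gap-only in the alignment")
        spans[pid] = span

    mean_start = _round_half_away(sum(s for s, _ in spans.values()) / len(spans))
    mean_end = _round_half_away(sum(e for _, e in spans.values()) / len(spans))

    rows = []
    for pid in ids:
        row = aln[pid]
        n_term = sum(1 for c in row[: mean_start - 1] if c not in GAP_CHARS)
        c_term = sum(1 for c in row[mean_end:] if c not in GAP_CHARS)
        rows.append(
            {
                "protein_id": pid,
                "n_term_extension": n_term,
                "c_term_extension": c_term,
                "long_extension_flag": n_term > LONG_EXTENSION_AA
                or c_term > LONG_EXTENSION_AA,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def read_signal_peptides(path: str | Path) -> dict[str, bool]:
    """Read external signal-peptide calls from a two-column TSV (id, boolean).

    Signal peptides are predicted by external tools; this toolkit only ingests
    their verdicts.
    """
    truthy = {"true", "1", "yes", "y", "t"}
    falsy = {"false", "0", "no", "n", "f"}
    calls: dict[str, bool] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", line=lineno
                )
            pid, value = parts
            lowered = value.strip().lower()
            if lowered in truthy:
                calls[pid] = True
            elif lowered in falsy:
                calls[pid] = False
            else:
                raise ParseError(f"unrecognised boolean {value!r}", line=lineno)
    return calls


def call_proteins(
    alignment,
    residue_map: ResidueMap,
    signal_peptides: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Classify every protein in the alignment.

    Returns one row per protein: key-residue count, count of key columns that
    are gapped, the Cld call, terminal extensions measured against the mean
    Cld span (zero when no protein qualifies as Cld), and the ingested
    signal-peptide verdict (pandas NA when unknown).
    """
    aln = as_mapping(alignment)
    records = []
    for pid in aln:
        profile = key_residue_profile(pid, aln, residue_map)
        n_match = profile.count("match")
        records.append(
            {
                "protein_id": pid,
                "n_key_residues": n_match,
                "n_gap_key_columns": profile.count("gap"),
                "is_cld": classify_cld(n_match),
            }
        )
    calls = pd.DataFrame(records).set_index("protein_id")

    cld_ids = calls.index[calls["is_cld"]].tolist()
    calls["n_term_extension"] = 0
    calls["c_term_extension"] = 0
    calls["long_extension_flag"] = False
    if cld_ids:
        ext = terminal_extensions(aln, cld_ids)
        calls.loc[ext.index, "n_term_extension"] = ext["n_term_extension"]
        calls.loc[ext.index, "c_term_extension"] = ext["c_term_extension"]
        calls.loc[ext.index, "long_extension_flag"] = ext["long_extension_flag"]

    if signal_peptides is None:
        calls["signal_peptide"] = pd.NA
    else:
        calls["signal_peptide"] = calls.index.map(
            lambda pid: signal_peptides.get(pid, pd.NA)
        )
    return calls.reset_index()
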