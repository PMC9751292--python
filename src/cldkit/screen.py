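"""Screening genomes for (per)chlorate-reductase co-presence.

Enzymes of the DMSO reductase family can reduce perchlorate or chlorate to
chlorite, either as dedicated respiratory reductases (Pcr, Clr) or
co-metabolically (e.g. nitrate reductases). A genome that encodes chlorite
dismutase but *no* such enzyme cannot plausibly derive its chlorite from
(per)chlorate reduction — flagging an oxidative chlorite source instead. The
profile-HMM searches themselves are run externally with standard tools; this
module parses their tabular output (HMMER ``tblout``/``domtblout``) and applies
the co-presence logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParameterError, ParseError

__all__ = [
    "HmmHit",
    "parse_hmm_table",
    "classify_genomes",
    "NON_PERCHLORATE_REDUCER",
    "POTENTIAL_REDUCER",
    "NO_CLD",
]

NON_PERCHLORATE_REDUCER = "non_perchlorate_reducer"
POTENTIAL_REDUCER = "potential_reducer"
NO_CLD = "no_cld"

DEFAULT_EVALUE_CUTOFF = 1e-5

# minimum whitespace-separated fields before the free-text description, and
# the indices of the query model name, full-sequence E-value and bit score
_DIALECTS = {
    "tblout": (18, 2, 4, 5),
    "domtblout": (22, 3, 6, 7),
}


@dataclass(frozen=True)
class HmmHit:
    """One target/query hit from a HMMER tabular file."""

    target_id: str
    query_name: str
    evalue: float
    score: float
    genome_id: str | None = None


def parse_hmm_table(
    path: str | Path,
    dialect: str = "tblout",
    protein_to_genome: Mapping[str, str] | None = None,
) -> list[HmmHit]:
    """Parse HMMER ``tblout`` or ``domtblout`` text output.

    ``#`` comment lines are skipped. Fields are whitespace-delimited with a
    trailing free-text description; only the target id, query model name and
    full-sequence E-value/score are retained. ``protein_to_genome`` supplies
    each hit's genome id (hits without a mapping keep ``genome_id=None``).
    """
    if dialect not in _DIALECTS:
        raise ParameterError(
            f"dialect must be one of {sorted(_DIALECTS)}, got {dialect!r}"
        )
    min_fields, query_idx, evalue_idx, score_idx = _DIALECTS[dialect]
    hits: list[HmmHit] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(None, min_fields)
            if len(fields) < min_fields:
                raise ParseError(
                    f"truncated {dialect} line: expected >= {min_fields} fields, "
                    f"got {len(fields)}",
                    line=lineno,
                )
            target = fields[0]
            query = fields[query_idx]
            try:
                evalue = float(fields[evalue_idx])
                score = float(fields[score_idx])
            except ValueError:
                raise ParseError(
                    f"non-numeric E-value/score fields "
                    f"{fields[evalue_idx]!r}/{fields[score_idx]!r}",
                    line=lineno,
                ) from None
            if evalue < 0:
                raise ParseError(f"negative E-value {evalue}", line=lineno)
            genome = (
                protein_to_genome.get(target) if protein_to_genome is not None else None
            )
            hits.append(
                HmmHit(
                    target_id=target,
                    query_name=query,
                    evalue=evalue,
                    score=score,
                    genome_id=genome,
                )
            )
    return hits


def classify_genomes(
    cld_by_genome: Mapping[str, bool],
    hits: Iterable[HmmHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> pd.DataFrame:
    """Classify genomes by Cld and (per)chlorate-reductase co-presence.

    ``cld_by_genome`` maps every screened genome id to whether it encodes Cld.
    A genome ``has_pcra`` when any of its hits passes the E-value cutoff
    (``evalue <= evalue_cutoff``). Classification:

    - ``non_perchlorate_reducer``: Cld present, no passing reductase hit —
      the genome's chlorite must come from something other than (per)chlorate
      reduction;
    - ``potential_reducer``: Cld present alongside a passing reductase hit;
    - ``no_cld``: no Cld, regardless of reductase hits.
    """
    if not evalue_cutoff > 0:
        raise ParameterError(f"evalue_cutoff must be > 0, got {evalue_cutoff}")
    passing: set[str] = set()
    for hit in hits:
        if hit.genome_id is not None and hit.evalue <= evalue_cutoff:
            passing.add(hit.genome_id)

    rows = []
    for genome_id in sorted(cld_by_genome):
        has_cld = bool(cld_by_genome[genome_id])
        has_pcra = genome_id in passing
        if not has_cld:
            classification = NO_CLD
        elif has_pcra:
            classification = POTENTIAL_REDUCER
        else:
            classification = NON_PERCHLORATE_REDUCER
        rows.append(
            {
                "genome_id": genome_id,
                "has_cld": has_cld,
                "has_pcra": has_pcra,
                "classification": classification,
            }
        )
    return pd.DataFrame(
        rows, columns=["genome_id", "has_cld", "has_pcra", "classification"]
    )
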