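"""Protein subfamily assignment for neighborhood proteins.

Subfamilies are clusters of homologous proteins drawn from the genomic
neighborhoods; each becomes one node of the co-occurrence network. Two routes
produce the assignment: importing the standard two-column representative/member
cluster output of an external tool (the authoritative route for reproducing
published numbers), or a native greedy centroid clusterer that joins a protein
to the first representative sharing enough k-mer content at sufficient mutual
coverage — a deterministic approximation adequate for synthetic benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ConsistencyError, EmptyInputError, ParseError

__all__ = [
    "SubfamilyAssignment",
    "read_fasta",
    "import_cluster_tsv",
    "write_cluster_tsv",
    "greedy_cluster",
    "force_cld_subfamilies",
]

CLD_SUBFAMILY_IDS = ("cld_1", "cld_2")


@dataclass
class SubfamilyAssignment:
    """Protein -> subfamily mapping with per-subfamily representatives.

    Every protein maps to exactly one subfamily and each subfamily's
    representative is one of its members.
    """

    membership: dict[str, str] = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rep in self.representatives.items():
            if self.membership.get(rep) != sid:
                raise ConsistencyError(
                    f"representative {rep!r} of subfamily {sid!r} is not a member"
                )

    def subfamily_of(self, protein_id: str) -> str:
        return self.membership[protein_id]

    @property
    def n_subfamilies(self) -> int:
        return len(self.representatives)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sid in self.membership.values():
            out[sid] = out.get(sid, 0) + 1
        return out

    def members(self, subfamily_id: str) -> list[str]:
        return sorted(p for p, s in self.membership.items() if s == subfamily_id)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered {id: sequence} map."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ParseError(f"duplicate sequence id {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
    return seqs


def import_cluster_tsv(path: str | Path) -> SubfamilyAssignment:
    """Ingest representative TAB member cluster output.

    Subfamilies are keyed by their representative id. A member listed under
    two different representatives is an inconsistency and is rejected.
    """
    membership: dict[str, str] = {}
    representatives: dict[str, str] = {}
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
            rep, member = parts
            if not rep or not member:
                raise ParseError("empty representative or member id", line=lineno)
            if member in membership and membership[member] != rep:
                raise ConsistencyError(
                    f"member {member!r} listed under representatives "
                    f"{membership[member]!r} and {rep!r}"
                )
            membership[member] = rep
            representatives.setdefault(rep, rep)
    # representatives are implicitly members of their own subfamily
    for rep in representatives:
        membership.setdefault(rep, rep)
    return SubfamilyAssignment(membership=membership, representatives=representatives)


def write_cluster_tsv(assignment: SubfamilyAssignment, path: str | Path) -> None:
    """Write representative TAB member lines (representative first, then
    members sorted by id) — the same dialect :func:`import_cluster_tsv` reads."""
    with open(path, "w") as handle:
        for sid in sorted(assignment.representatives):
            rep = assignment.representatives[sid]
            handle.write(f"{rep}\t{rep}\n")
            for member in assignment.members(sid):
                if member != rep:
                    handle.write(f"{rep}\t{member}\n")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    proteins: Mapping[str, str],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    kmer: int = 5,
) -> SubfamilyAssignment:
    """Deterministic greedy centroid clustering by k-mer containment.

    Proteins are processed in decreasing length order (ties by id). Each
    protein joins the first existing representative whose k-mer containment
    similarity — shared k-mers over the smaller k-mer set — is at least
    ``min_identity``, provided the implied matched length covers at least
    ``min_coverage`` of *both* sequences; otherwise it founds a new subfamily.

    This is a stand-in for alignment-based clustering tools: the similarity
    criterion is k-mer containment, not alignment statistics, so external
    cluster files remain the authoritative route where exact reproduction of
    published subfamilies matters.
    """
    if not proteins:
        return SubfamilyAssignment()
    for pid, seq in proteins.items():
        if not seq:
            raise EmptyInputError(f"protein {pid!r} has an empty sequence")
        if len(seq) < kmer:
            raise EmptyInputError(
                f"protein {pid!r} is shorter ({len(seq)} aa) than the k-mer size {kmer}"
            )

    order = sorted(proteins, key=lambda pid: (-len(proteins[pid]), pid))
    rep_kmers: dict[str, set[str]] = {}
    rep_order: list[str] = []
    membership: dict[str, str] = {}

    for pid in order:
        seq = proteins[pid].upper()
        kset = _kmers(seq, kmer)
        chosen = None
        for rep in rep_order:
            rset = rep_kmers[rep]
            shared = len(kset & rset)
            if shared == 0:
                continue
            identity = shared / min(len(kset), len(rset))
            if identity < min_identity:
                continue
            matched = shared + kmer - 1
            if (
                matched / len(seq) >= min_coverage
                and matched / len(proteins[rep]) >= min_coverage
            ):
                chosen = rep
                break
        if chosen is None:
            rep_kmers[pid] = kset
            rep_order.append(pid)
            membership[pid] = pid
        else:
            membership[pid] = chosen

    representatives = {rep: rep for rep in rep_order}
    return SubfamilyAssignment(membership=membership, representatives=representatives)


def force_cld_subfamilies(
    assignment: SubfamilyAssignment,
    cld_lineages: Mapping[str, int],
) -> SubfamilyAssignment:
    """Pin Cld proteins to the fixed subfamily ids ``cld_1`` / ``cld_2``.

    ``cld_lineages`` maps Cld protein ids to their lineage number (1 or 2).
    The two Cld lineages are treated as distinct, fixed subfamilies so that
    linkage tables list them under stable ids regardless of how the generic
    clusterer grouped them.
    """
    membership = dict(assignment.membership)
    representatives = {
        sid: rep
        for sid, rep in assignment.representatives.items()
        if sid not in CLD_SUBFAMILY_IDS
    }
    firsts: dict[str, str] = {}
    for pid in sorted(cld_lineages):
        lineage = cld_lineages[pid]
        if lineage not in (1, 2):
            raise ConsistencyError(
                f"Cld lineage for {pid!r} must be 1 or 2, got {lineage!r}"
            )
        sid = f"cld_{lineage}"
        membership[pid] = sid
        firsts.setdefault(sid, pid)
    for sid, rep in firsts.items():
        representatives[sid] = rep
    # drop subfamilies emptied by the reassignment
    live = set(membership.values())
    representatives = {
        sid: rep for sid, rep in representatives.items() if sid in live
    }
    for sid, rep in list(representatives.items()):
        if membership.get(rep) != sid:
            representatives[sid] = min(
                p for p, s in membership.items() if s == sid
            )
    return SubfamilyAssignment(membership=membership, representatives=representatives)


def assignment_from_truth(truth: Iterable[tuple[str, str]]) -> SubfamilyAssignment:
    """Build an assignment from (protein_id, subfamily_id) pairs, choosing the
    lexicographically first member of each subfamily as its representative."""
    membership = {pid: sid for pid, sid in truth}
    reps: dict[str, str] = {}
    for pid in sorted(membership):
        reps.setdefault(membership[pid], pid)
    return SubfamilyAssignment(membership=membership, representatives=reps)
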