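"""Organism-scoped redundancy marking and removal.

Three rules mark entries redundant *within an organism group*: identical
sequence, shared UniProt ID, and >= threshold percent identity under global
pairwise alignment.  Cross-organism identical sequences are never marked.

Identity convention: matches / alignment_length of a global alignment with
match +1, mismatch 0, gap -1 (no distinct open/extend); gap columns count in
the denominator.  This is the strictest common convention and approximates
an MSA-column identity pairwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align

from .core import ProteinRecord


class RedundancyReason(str, enum.Enum):
    IDENTICAL = "identical"
    SAME_UNIPROT = "same_uniprot"
    HIGH_IDENTITY = "high_identity"


_REASON_PRIORITY = {
    RedundancyReason.IDENTICAL: 0,
    RedundancyReason.SAME_UNIPROT: 1,
    RedundancyReason.HIGH_IDENTITY: 2,
}


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    representative: str
    reason: RedundancyReason


@dataclass
class RedundancyReport:
    clusters: list[Cluster]
    n_input: int
    n_kept: int
    n_removed: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + self.n_removed:
            raise ValueError("conservation violated: n_input != n_kept + n_removed")

    @property
    def removed_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out.update(m for m in c.members if m != c.representative)
        return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Symmetric by construction (the pair is ordered canonically before
    aligning).  Empty sequences are a domain error.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    alignment_length = aln.shape[1]
    return 100.0 * counts.identities / alignment_length


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        # best (lowest-priority-value) merge reason seen in each component
        self.reason: list[RedundancyReason | None] = [None] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int, reason: RedundancyReason) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            root = ra
        else:
            root = min(ra, rb)
            other = max(ra, rb)
            self.parent[other] = root
            if self.reason[other] is not None and (
                self.reason[root] is None
                or _REASON_PRIORITY[self.reason[other]] < _REASON_PRIORITY[self.reason[root]]
            ):
                self.reason[root] = self.reason[other]
        if self.reason[root] is None or _REASON_PRIORITY[reason] < _REASON_PRIORITY[
            self.reason[root]
        ]:
            self.reason[root] = reason


def _max_possible_identity(len_a: int, len_b: int) -> float:
    # matches <= min length, alignment length >= max length
    return 100.0 * min(len_a, len_b) / max(len_a, len_b)


def mark_redundant(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 95.0,
    max_group_size: int = 2000,
) -> RedundancyReport:
    """Cluster redundant entries within each organism group.

    Within a group (processed in deterministic order, sorted by uniprot_id
    then sequence): exact-duplicate and same-UniProt-ID clusters are formed
    first, then greedy single-linkage on ``pairwise_identity >= threshold``.
    The representative of each cluster is the lexicographically smallest
    uniprot_id.  All-pairs alignment is quadratic, so organism groups larger
    than ``max_group_size`` are refused; pre-bucket by length for full-scale
    runs.
    """
    by_organism: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_organism.setdefault(rec.organism, []).append(rec)

    clusters: list[Cluster] = []
    for organism in sorted(by_organism):
        group = sorted(by_organism[organism], key=lambda r: (r.uniprot_id, r.sequence))
        if len(group) > max_group_size:
            raise ValueError(
                f"organism group {organism!r} has {len(group)} entries "
                f"(> max_group_size={max_group_size}); pre-bucket by length"
            )
        uf = _UnionFind(len(group))

        seen_seq: dict[str, int] = {}
        for i, rec in enumerate(group):
            if rec.sequence in seen_seq:
                uf.union(seen_seq[rec.sequence], i, RedundancyReason.IDENTICAL)
            else:
                seen_seq[rec.sequence] = i

        seen_id: dict[str, int] = {}
        for i, rec in enumerate(group):
            if rec.uniprot_id in seen_id:
                uf.union(seen_id[rec.uniprot_id], i, RedundancyReason.SAME_UNIPROT)
            else:
                seen_id[rec.uniprot_id] = i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if uf.find(i) == uf.find(j):
                    continue
                la, lb = len(group[i].sequence), len(group[j].sequence)
                if _max_possible_identity(la, lb) < identity_threshold:
                    continue
                ident = pairwise_identity(group[i].sequence, group[j].sequence)
                if ident >= identity_threshold:
                    uf.union(i, j, RedundancyReason.HIGH_IDENTITY)

        components: dict[int, list[int]] = {}
        for i in range(len(group)):
            components.setdefault(uf.find(i), []).append(i)
        for root, members in sorted(components.items()):
            if len(members) < 2:
                continue
            # members may share a uniprot_id; one entry per record index
            ids = tuple(sorted(group[i].uniprot_id for i in members))
            reason = uf.reason[root] or RedundancyReason.HIGH_IDENTITY
            clusters.append(
                Cluster(members=ids, representative=min(ids), reason=reason)
            )

    n_removed = sum(len(c.members) - 1 for c in clusters)
    return RedundancyReport(
        clusters=clusters,
        n_input=len(records),
        n_kept=len(records) - n_removed,
        n_removed=n_removed,
    )


def dedupe(
    records: Sequence[ProteinRecord], report: RedundancyReport
) -> list[ProteinRecord]:
    """Return representatives only, preserving input order.

    For clusters of records sharing a uniprot_id, the first occurrence of the
    representative id is kept.
    """
    if report.n_input != len(records):
        raise ValueError(
            f"report/record mismatch: report covers {report.n_input} records, "
            f"got {len(records)}"
        )
    known_ids = {r.uniprot_id for r in records}
    for c in report.clusters:
        unknown = set(c.members) - known_ids
        if unknown:
            raise ValueError(f"report names unknown records: {sorted(unknown)}")

    removal_budget: dict[str, int] = {}
    keep_budget: dict[str, int] = {}
    for c in report.clusters:
        for m in c.members:
            removal_budget[m] = removal_budget.get(m, 0) + 1
        keep_budget[c.representative] = keep_budget.get(c.representative, 0) + 1

    kept: list[ProteinRecord] = []
    for rec in records:
        rid = rec.uniprot_id
        if removal_budget.get(rid, 0) > 0:
            removal_budget[rid] -= 1
            if keep_budget.get(rid, 0) > 0:
                keep_budget[rid] -= 1
                kept.append(rec)
        else:
            kept.append(rec)
    return kept


def redundancy_table(
    records: Sequence[ProteinRecord], report: RedundancyReport
) -> pd.DataFrame:
    """Fully annotated table: every record with its redundancy flag."""
    cluster_of: dict[str, tuple[int, Cluster]] = {}
    for k, c in enumerate(report.clusters):
        for m in c.members:
            cluster_of[m] = (k, c)
    rows = []
    for rec in records:
        entry = cluster_of.get(rec.uniprot_id)
        if entry is None:
            rows.append((rec.uniprot_id, rec.organism, -1, True, False, ""))
        else:
            k, c = entry
            is_rep = rec.uniprot_id == c.representative
            rows.append(
                (rec.uniprot_id, rec.organism, k, is_rep, not is_rep, c.reason.value)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "member_id",
            "organism",
            "cluster_id",
            "representative_flag",
            "redundant",
            "reason",
        ],
    )


def write_report(
    records: Sequence[ProteinRecord], report: RedundancyReport, path: str | Path
) -> None:
    redundancy_table(records, report).to_csv(path, sep="\t", index=False)
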