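"""Motif scanning and TM-coverage assignment.

The scanner enumerates every 5-residue window with glycine at both ends,
including overlapping occurrences: poly-G runs such as ``GGGGGGG`` yield one
motif per admissible start.  The all-G window ``GGGGG`` is itself a valid
motif type, which is exactly why overlap-aware scanning matters — a
non-overlapping scanner systematically undercounts it.  A flag restores the
non-overlapping convention for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .core import (
    COVERAGE_LEVELS,
    STANDARD_RESIDUE_SET,
    MotifInstance,
    ProteinRecord,
    TMFeature,
)

logger = logging.getLogger(__name__)


@dataclass
class RejectionLog:
    """Windows excluded because an X position held a non-standard residue."""

    n_rejected: int = 0
    by_protein: dict[str, int] = field(default_factory=dict)

    def add(self, protein_ref: str, n: int) -> None:
        if n:
            self.n_rejected += n
            self.by_protein[protein_ref] = self.by_protein.get(protein_ref, 0) + n


def scan_motifs(
    sequence: str,
    overlapping: bool = True,
) -> list[tuple[int, str]]:
    """Return every (start, 5-mer) with G at window positions 1 and 5.

    Starts are 1-based and ascending.  Windows whose X1–X3 contain a
    non-standard residue are excluded (count them via :func:`scan_with_log`).
    Sequences shorter than 5 yield an empty list.
    """
    hits, _ = scan_with_log(sequence, overlapping=overlapping)
    return hits


def scan_with_log(
    sequence: str,
    overlapping: bool = True,
) -> tuple[list[tuple[int, str]], int]:
    """Like :func:`scan_motifs` but also returns the rejected-window count."""
    hits: list[tuple[int, str]] = []
    n_rejected = 0
    n = len(sequence)
    i = 0
    while i <= n - 5:
        if sequence[i] == "G" and sequence[i + 4] == "G":
            window = sequence[i : i + 5]
            if all(c in STANDARD_RESIDUE_SET for c in window[1:4]):
                hits.append((i + 1, window))
                if not overlapping:
                    i += 5
                    continue
            else:
                n_rejected += 1
        i += 1
    return hits, n_rejected


def tm_coverage(start: int, features: Sequence[TMFeature]) -> int:
    """TM coverage percent of the 5-residue window beginning at ``start``.

    Counts window residues covered by the *union* of the features — a residue
    inside two overlapping features counts once — and returns 20 per residue.
    """
    if start < 1:
        raise ValueError(f"start must be >= 1, got {start}")
    covered = 0
    for pos in range(start, start + 5):
        if any(f.covers(pos) for f in features):
            covered += 1
    result = 20 * covered
    assert result in COVERAGE_LEVELS
    return result


def extract_instances(
    records: Sequence[ProteinRecord],
    overlapping: bool = True,
    rejection_log: RejectionLog | None = None,
) -> list[MotifInstance]:
    """Scan every record and attach TM coverage to each hit.

    Ordering is deterministic: record order, then ascending start.
    """
    instances: list[MotifInstance] = []
    for rec in records:
        hits, n_rej = scan_with_log(rec.sequence, overlapping=overlapping)
        if rejection_log is not None:
            rejection_log.add(rec.uniprot_id, n_rej)
        elif n_rej:
            logger.info("%s: rejected %d non-standard windows", rec.uniprot_id, n_rej)
        for start, motif in hits:
            instances.append(
                MotifInstance(
                    protein_ref=rec.uniprot_id,
                    motif=motif,
                    start=start,
                    tm_coverage=tm_coverage(start, rec.tm_features),
                )
            )
    return instances
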