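"""Positional amino-acid composition at X1/X2/X3, log2 enrichment between
categories, and Fisher's exact tests with Benjamini–Hochberg FDR control.

Frequencies are occurrence-weighted by default (every motif instance counts);
pass a deduplicated motif set for unique-motif weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import STANDARD_RESIDUES, STANDARD_RESIDUE_SET, MotifInstance

X_POSITIONS = ("X1", "X2", "X3")
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}

#: Significance tiers keyed by their q-value ceilings, most stringent first.
TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class CompositionProfile:
    """Per-position residue counts and percent frequencies for one category.

    ``counts`` is a 3 x 20 integer matrix (X1..X3 by standard residues in
    alphabetical order); each row of ``freq`` sums to 100 (within numerical
    tolerance).
    """

    group: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 20):
            raise ValueError(f"counts must be 3x20, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def position_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def freq(self) -> np.ndarray:
        """Percent frequencies, each X position scaled independently to 100."""
        totals = self.position_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / totals[:, None]
        return np.where(totals[:, None] > 0, out, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        freq = self.freq
        for p, pos in enumerate(X_POSITIONS):
            for r, aa in enumerate(STANDARD_RESIDUES):
                rows.append(
                    (self.group, pos, aa, int(self.counts[p, r]), freq[p, r])
                )
        return pd.DataFrame(
            rows, columns=["group", "position", "residue", "count", "percent"]
        )


def positional_frequencies(
    motifs: Iterable[str] | Iterable[MotifInstance], group: str
) -> CompositionProfile:
    """Count residues at motif string positions 2–4 (the X positions).

    Accepts either motif strings or instances; every element must be a valid
    GXXXG 5-mer over the standard residues (non-standard windows are excluded
    upstream — encountering one here is an error).
    """
    counts = np.zeros((3, 20), dtype=np.int64)
    for item in motifs:
        motif = item.motif if isinstance(item, MotifInstance) else item
        if len(motif) != 5:
            raise ValueError(f"not a 5-mer: {motif!r}")
        for p, aa in enumerate(motif[1:4]):
            if aa not in STANDARD_RESIDUE_SET:
                raise ValueError(f"non-standard residue {aa!r} in motif {motif!r}")
            counts[p, _RESIDUE_INDEX[aa]] += 1
    return CompositionProfile(group=group, counts=counts)


def log2_enrichment(
    profile_a: CompositionProfile,
    profile_b: CompositionProfile,
    pseudo_freq: float | None = None,
) -> np.ndarray:
    """Elementwise log2((f_a + pseudo) / (f_b + pseudo)) on fractional
    frequencies.

    ``pseudo_freq=None`` uses half a count per profile position
    (0.5 / position_total), giving finite enrichment for absent residues.
    With ``pseudo_freq=0`` a zero in b against a nonzero in a yields +inf.
    """
    fa = profile_a.freq / 100.0
    fb = profile_b.freq / 100.0
    if pseudo_freq is None:
        ta = np.maximum(profile_a.position_totals, 1).astype(float)
        tb = np.maximum(profile_b.position_totals, 1).astype(float)
        pa = 0.5 / ta[:, None]
        pb = 0.5 / tb[:, None]
    else:
        pa = pb = float(pseudo_freq)
    # 0/0 cells (residue absent in both) are NaN by design
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2((fa + pa) / (fb + pb))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), clipped to [p, 1]."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing in sorted order (step-up)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _tier(q: float) -> str:
    for threshold, label in TIER_THRESHOLDS:
        if q < threshold:
            return label
    return "ns"


def fisher_fdr_tests(
    profile_a: CompositionProfile,
    profile_b: CompositionProfile,
    comparison: str = "",
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per (position, residue) with BH FDR.

    For residue r at one position the 2x2 table is
    [[a_r, A - a_r], [b_r, B - b_r]] with A, B the position totals.  The FDR
    family is this comparison's 60 tests (3 positions x 20 residues);
    positions with a zero total are skipped with a flag column.
    """
    rows = []
    for p, pos in enumerate(X_POSITIONS):
        a_total = int(profile_a.position_totals[p])
        b_total = int(profile_b.position_totals[p])
        skipped = a_total == 0 or b_total == 0
        for r, aa in enumerate(STANDARD_RESIDUES):
            if skipped:
                rows.append((comparison, pos, aa, np.nan, True))
                continue
            a_r = int(profile_a.counts[p, r])
            b_r = int(profile_b.counts[p, r])
            _, pval = sps.fisher_exact(
                [[a_r, a_total - a_r], [b_r, b_total - b_r]], alternative="two-sided"
            )
            rows.append((comparison, pos, aa, float(pval), False))
    df = pd.DataFrame(
        rows, columns=["comparison", "position", "residue", "fisher_p", "skipped"]
    )
    enrichment = log2_enrichment(profile_a, profile_b)
    df["log2_enrichment"] = [
        enrichment[X_POSITIONS.index(pos), _RESIDUE_INDEX[aa]]
        for pos, aa in zip(df["position"], df["residue"])
    ]
    valid = ~df["skipped"]
    df["fdr_q"] = np.nan
    if valid.any():
        df.loc[valid, "fdr_q"] = benjamini_hochberg(df.loc[valid, "fisher_p"].values)
    df["tier"] = [("ns" if np.isnan(q) else _tier(q)) for q in df["fdr_q"]]
    return df[
        [
            "comparison",
            "position",
            "residue",
            "log2_enrichment",
            "fisher_p",
            "fdr_q",
            "tier",
            "skipped",
        ]
    ]
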