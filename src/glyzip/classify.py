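"""TM-coverage threshold classification and unique-motif partitioning.

At a threshold t an instance is TM iff its coverage >= t; everything else —
including sub-threshold partial coverage — is non-TM at that t.  Unique motif
strings then partition into TM-only / non-TM-only / shared by whether their
instances occur on one side, the other, or both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy import stats as sps

from .core import COVERAGE_LEVELS, MotifInstance

VALID_THRESHOLDS = (20, 40, 60, 80, 100)


@dataclass
class ThresholdPartition:
    t: int
    n_tm_instances: int
    n_nontm_instances: int
    unique_tm: set[str]
    unique_nontm: set[str]

    @property
    def shared(self) -> set[str]:
        return self.unique_tm & self.unique_nontm

    @property
    def tm_only(self) -> set[str]:
        return self.unique_tm - self.unique_nontm

    @property
    def nontm_only(self) -> set[str]:
        return self.unique_nontm - self.unique_tm


@dataclass
class SweepMetrics:
    """Per-threshold classification ratios and adjacent-threshold chi-square."""

    thresholds: list[int]
    rows: list[dict] = field(default_factory=list)
    chi2_vs_next: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _check_threshold(t: int) -> None:
    if t not in VALID_THRESHOLDS:
        raise ValueError(f"threshold must be one of {VALID_THRESHOLDS}, got {t}")


def classify_instances(
    instances: Sequence[MotifInstance], t: int
) -> tuple[list[MotifInstance], list[MotifInstance]]:
    """Split instances into (TM, non-TM) lists at threshold ``t``."""
    _check_threshold(t)
    tm = [i for i in instances if i.tm_coverage >= t]
    nontm = [i for i in instances if i.tm_coverage < t]
    return tm, nontm


def partition_unique(
    instances: Sequence[MotifInstance], t: int
) -> ThresholdPartition:
    """Set algebra over unique motif strings of the two instance classes."""
    tm, nontm = classify_instances(instances, t)
    return ThresholdPartition(
        t=t,
        n_tm_instances=len(tm),
        n_nontm_instances=len(nontm),
        unique_tm={i.motif for i in tm},
        unique_nontm={i.motif for i in nontm},
    )


def coverage_histogram(
    instances: Sequence[MotifInstance],
) -> dict[str, dict[int, dict[str, float]]]:
    """Coverage-level counts and percents, overall and within the TM subset.

    The TM subset comprises instances with coverage >= 20; its percents are
    reported relative to the subset total.  With no TM instances the subset
    histogram is empty and flagged via the ``tm_subset_empty`` key.
    """
    counts = {c: 0 for c in COVERAGE_LEVELS}
    for inst in instances:
        counts[inst.tm_coverage] += 1
    total = len(instances)
    overall = {
        c: {"count": counts[c], "percent": (100.0 * counts[c] / total) if total else 0.0}
        for c in COVERAGE_LEVELS
    }
    tm_total = sum(counts[c] for c in COVERAGE_LEVELS if c >= 20)
    tm_subset = {
        c: {"count": counts[c], "percent": 100.0 * counts[c] / tm_total}
        for c in COVERAGE_LEVELS
        if c >= 20 and tm_total
    }
    return {
        "overall": overall,
        "tm_subset": tm_subset,
        "tm_subset_empty": tm_total == 0,
    }


def chi2_independence(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square of independence on a 2x2 table, df=1, no continuity
    correction.  A zero expected cell yields (nan, nan)."""
    try:
        res = sps.chi2_contingency(table, correction=False)
    except ValueError:
        return (math.nan, math.nan)
    return (float(res.statistic), float(res.pvalue))


def sweep_metrics(
    instances: Sequence[MotifInstance],
    thresholds: Sequence[int] = VALID_THRESHOLDS,
) -> SweepMetrics:
    """Ratios per threshold plus chi-square between adjacent thresholds.

    The 2x2 tables are [TM count, non-TM count] at t versus the next t.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    for t in thresholds:
        _check_threshold(t)
    total = len(instances)
    metrics = SweepMetrics(thresholds=thresholds)
    counts: dict[int, tuple[int, int]] = {}
    for t in thresholds:
        tm, nontm = classify_instances(instances, t)
        counts[t] = (len(tm), len(nontm))
        tm_ratio = len(tm) / total if total else math.nan
        nontm_ratio = len(nontm) / total if total else math.nan
        metrics.rows.append(
            {
                "t": t,
                "n_tm": len(tm),
                "n_nontm": len(nontm),
                "tm_ratio": tm_ratio,
                "nontm_ratio": nontm_ratio,
                "tm_over_nontm": (len(tm) / len(nontm)) if len(nontm) else math.inf,
            }
        )
    for t, t_next in zip(thresholds, thresholds[1:]):
        table = [list(counts[t]), list(counts[t_next])]
        metrics.chi2_vs_next[(t, t_next)] = chi2_independence(table)
    return metrics
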