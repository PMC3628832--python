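"""Cohort-level disorder statistics.

Aggregates per-protein results into the dataset-level numbers a disorder
survey reports: the three-way disorder-content classification (highly
ordered < 10%, moderately disordered 10–30%, highly disordered > 30%), the
prevalence of long (>= 30 residue) disordered regions, CH-CDF quadrant
fractions, and the carrier/interval statistics of predicted disorder-based
binding sites (MoRFs and ANCHOR-indicated binding sites) from the annotation
table.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .binary_classifiers import QuadrantPoint
from .dataset_io import AnnotationRow
from .residue_profiles import DisorderMask, long_disordered_regions

__all__ = [
    "ContentClassScheme",
    "IntervalStats",
    "CohortSummary",
    "classify_content",
    "long_region_prevalence",
    "interval_stats",
    "quadrant_fractions",
    "cohort_summary",
]

CONTENT_CLASSES = ("highly_ordered", "moderately_disordered",
                   "highly_disordered")


@dataclass(frozen=True)
class ContentClassScheme:
    """Cutoffs for the three-way disorder-content classification.

    Values exactly at a cutoff belong to the middle class (the published
    inequalities are strict on both sides, leaving the boundary open).
    """

    low: float = 0.10
    high: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high < 1.0:
            raise ValueError("need 0 < low < high < 1")


def classify_content(fraction: float,
                     scheme: ContentClassScheme = ContentClassScheme()) -> str:
    """Class label for a disorder-content fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction < scheme.low:
        return "highly_ordered"
    if fraction <= scheme.high:
        return "moderately_disordered"
    return "highly_disordered"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class IntervalStats:
    """Carrier and count statistics for one interval annotation column."""

    cohort_size: int
    n_with_any: int
    total_intervals: int
    mean_per_protein: float
    mean_per_carrier: float | None
    percent_with_any: int


def interval_stats(rows: Sequence[AnnotationRow],
                   which: Literal["morfs", "aibs"]) -> IntervalStats:
    """Carrier statistics over the valid (unflagged) intervals of a cohort.

    ``percent_with_any`` is rounded half-away-from-zero to the nearest
    integer; ``mean_per_carrier`` is None when no protein carries an
    interval.
    """
    if not rows:
        raise ValueError("empty cohort")
    if which not in ("morfs", "aibs"):
        raise ValueError(f"unknown interval kind {which!r}")
    n = len(rows)
    per_row = [len(getattr(r, which)) for r in rows]
    carriers = sum(1 for k in per_row if k > 0)
    total = sum(per_row)
    return IntervalStats(
        cohort_size=n,
        n_with_any=carriers,
        total_intervals=total,
        mean_per_protein=total / n,
        mean_per_carrier=total / carriers if carriers else None,
        percent_with_any=_round_half_away(100.0 * carriers / n),
    )


def long_region_prevalence(masks: Sequence[DisorderMask],
                           min_len: int = 30) -> float:
    """Percentage of proteins with at least one disordered run >= min_len.

    Reported to one decimal place.
    """
    if not masks:
        raise ValueError("empty mask list")
    carriers = sum(
        1 for m in masks if long_disordered_regions(m, min_len=min_len))
    return round(100.0 * carriers / len(masks), 1)


def quadrant_fractions(
    points: Sequence[QuadrantPoint],
) -> dict[str, float]:
    """Fraction of proteins per CH-CDF quadrant, plus the combined
    mostly-disordered fraction Q3+Q4."""
    if not points:
        raise ValueError("empty point list")
    counts = Counter(p.quadrant for p in points)
    n = len(points)
    out = {q: counts.get(q, 0) / n for q in ("Q1", "Q2", "Q3", "Q4")}
    out["Q3+Q4"] = out["Q3"] + out["Q4"]
    return out


@dataclass
class CohortSummary:
    """Aggregated cohort report; profile-dependent fields are None when the
    corresponding inputs were not supplied."""

    cohort_size: int
    morf_stats: IntervalStats | None = None
    aibs_stats: IntervalStats | None = None
    content_class_counts: dict[str, int] | None = None
    long_region_prevalence_pct: float | None = None
    quadrant_fractions: dict[str, float] | None = None
    per_group: dict[str, dict] = field(default_factory=dict)
    flagged_intervals: dict[str, list[str]] = field(default_factory=dict)


def cohort_summary(
    rows: Sequence[AnnotationRow],
    masks: Mapping[str, DisorderMask] | None = None,
    points: Sequence[QuadrantPoint] | None = None,
    scheme: ContentClassScheme = ContentClassScheme(),
    min_len: int = 30,
) -> CohortSummary:
    """Aggregate annotation rows, disorder masks and CH-CDF points.

    ``masks`` maps accession -> DisorderMask and must cover exactly the row
    accessions when given; ``points`` likewise by accession.  With rows only,
    the profile-dependent fields are left unpopulated.  The per-complex-group
    breakdown (row counts, carrier counts) always comes from the rows.
    """
    if not rows:
        raise ValueError("empty cohort")
    accs = [r.accession for r in rows]
    summary = CohortSummary(cohort_size=len(rows))
    summary.morf_stats = interval_stats(rows, "morfs")
    summary.aibs_stats = interval_stats(rows, "aibs")
    summary.flagged_intervals = {
        r.accession: r.flagged_morfs + r.flagged_aibs
        for r in rows if r.flagged_morfs or r.flagged_aibs
    }

    if masks is not None:
        missing = [a for a in accs if a not in masks]
        if missing:
            raise ValueError(f"masks missing for accessions: {missing}")
        from .residue_profiles import disorder_content
        contents = {a: disorder_content(masks[a]) for a in accs}
        counts = Counter(classify_content(contents[a], scheme) for a in accs)
        summary.content_class_counts = {c: counts.get(c, 0)
                                        for c in CONTENT_CLASSES}
        summary.long_region_prevalence_pct = long_region_prevalence(
            [masks[a] for a in accs], min_len=min_len)

    if points is not None:
        by_acc = {p.accession: p for p in points}
        missing = [a for a in accs if a not in by_acc]
        if missing:
            raise ValueError(f"points missing for accessions: {missing}")
        summary.quadrant_fractions = quadrant_fractions(
            [by_acc[a] for a in accs])

    for group in sorted({r.complex_group for r in rows}):
        grows = [r for r in rows if r.complex_group == group]
        summary.per_group[group] = {
            "n": len(grows),
            "morf_carriers": sum(1 for r in grows if r.morfs),
            "aibs_carriers": sum(1 for r in grows if r.aibs),
        }
    return summary
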