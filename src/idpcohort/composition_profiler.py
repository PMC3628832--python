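"""Fractional-difference amino-acid composition profiling.

Compares the pooled residue composition of a query protein set against a
reference (typically ordered) set residue by residue:

    difference(X) = (C_X - C_ref) / C_ref

so a residue absent from the query scores exactly -1 and a residue twice as
frequent scores +1.  Residues are displayed ranked by disorder-promoting
potential, so a disordered cohort shows the characteristic profile —
depleted in order-promoting residues on the left, enriched in
disorder-promoting residues on the right.  Confidence intervals come from a
protein-level bootstrap within the query set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset_io import ProteinRecord, STANDARD_AA, packaged_data_path

__all__ = [
    "CompositionVector",
    "CompositionProfile",
    "ResidueOrder",
    "composition",
    "fractional_difference",
    "bootstrap_profile",
    "load_composition",
    "load_residue_order",
]


@dataclass(frozen=True)
class CompositionVector:
    """Fractions of the 20 standard residues in a protein set."""

    fractions: dict[str, float]
    total_residues: int

    def __post_init__(self) -> None:
        if set(self.fractions) != set(STANDARD_AA):
            raise ValueError("composition must cover exactly the 20 "
                             "standard residues")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9 or min(self.fractions.values()) < 0:
            raise ValueError("fractions must be non-negative and sum to 1")


@dataclass(frozen=True)
class ResidueOrder:
    """Display permutation of the 20 residues (order- to disorder-promoting)."""

    residues: tuple[str, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        if sorted(self.residues) != sorted(STANDARD_AA):
            raise ValueError("residue order must be a permutation of the 20 "
                             "standard residues")


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue fractional differences of a query set vs a reference.

    ``differences[X]`` is NaN where the reference fraction is zero (the ratio
    is undefined there, not infinite).  ``ci`` maps residues to (lo, hi)
    bootstrap percentile bounds when computed.
    """

    differences: dict[str, float]
    query_label: str
    reference_label: str
    order: ResidueOrder
    ci: dict[str, tuple[float, float]] | None = None


def composition(records: Sequence[ProteinRecord]) -> CompositionVector:
    """Pooled residue composition of a protein set (ambiguity codes skipped)."""
    if not records:
        raise ValueError("need at least one protein")
    counts = {aa: 0 for aa in STANDARD_AA}
    for rec in records:
        for c in rec.sequence:
            if c in counts:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues in the input set")
    return CompositionVector({aa: n / total for aa, n in counts.items()},
                             total)


def fractional_difference(
    query: CompositionVector,
    reference: CompositionVector,
    order: ResidueOrder | None = None,
    query_label: str = "query",
    reference_label: str = "reference",
) -> CompositionProfile:
    """Elementwise ``(C_query - C_ref) / C_ref`` per residue.

    Residues with zero reference fraction are reported as NaN with a
    warning rather than +/-infinity.
    """
    if order is None:
        order = load_residue_order()
    diffs: dict[str, float] = {}
    for aa in STANDARD_AA:
        ref = reference.fractions[aa]
        if ref == 0.0:
            warnings.warn(
                f"reference fraction for {aa} is zero; difference undefined",
                stacklevel=2,
            )
            diffs[aa] = math.nan
        else:
            diffs[aa] = (query.fractions[aa] - ref) / ref
    return CompositionProfile(diffs, query_label, reference_label, order)


def _count_matrix(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Per-protein residue count matrix (n_proteins x 20)."""
    aa_index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    mat = np.zeros((len(records), 20), dtype=np.int64)
    for i, rec in enumerate(records):
        for c in rec.sequence:
            j = aa_index.get(c)
            if j is not None:
                mat[i, j] += 1
    return mat


def bootstrap_profile(
    query_records: Sequence[ProteinRecord],
    reference: CompositionVector | Sequence[ProteinRecord],
    n_boot: int = 10000,
    seed: int | None = None,
    order: ResidueOrder | None = None,
    ci_level: float = 0.95,
    query_label: str = "query",
    reference_label: str = "reference",
) -> CompositionProfile:
    """Fractional-difference profile with bootstrap percentile CIs.

    Proteins (not residues) are resampled with replacement within the query
    set — the cohort, not the residue pool, is the sampling unit.
    Deterministic for a fixed seed.
    """
    if len(query_records) < 2:
        raise ValueError("bootstrap needs at least 2 query proteins")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CIs will be unstable",
                      stacklevel=2)
    if not isinstance(reference, CompositionVector):
        reference = composition(reference)
    point = fractional_difference(
        composition(query_records), reference, order=order,
        query_label=query_label, reference_label=reference_label)

    rng = np.random.default_rng(seed)
    counts = _count_matrix(query_records)
    n = counts.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_counts = counts[idx].sum(axis=1)            # (n_boot, 20)
    totals = boot_counts.sum(axis=1, keepdims=True).astype(float)
    ref = np.array([reference.fractions[aa] for aa in STANDARD_AA])
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_diff = (boot_counts / totals - ref) / ref
    alpha = (1.0 - ci_level) / 2.0
    lo = np.nanpercentile(boot_diff, 100 * alpha, axis=0)
    hi = np.nanpercentile(boot_diff, 100 * (1 - alpha), axis=0)
    ci = {aa: (float(lo[j]), float(hi[j]))
          for j, aa in enumerate(STANDARD_AA)}
    return CompositionProfile(point.differences, point.query_label,
                              point.reference_label, point.order, ci=ci)


def load_composition(name_or_path: str | Path) -> CompositionVector:
    """Load a packaged (by short name) or user composition file.

    Short names: ``ordered`` and ``disordered`` resolve to the packaged
    synthetic stand-in reference compositions.  File format: 20 lines
    ``residue fraction``; ``#`` comments ignored.
    """
    aliases = {
        "ordered": packaged_data_path("composition_ordered_synthetic.tsv"),
        "disordered": packaged_data_path(
            "composition_disordered_synthetic.tsv"),
    }
    src = aliases.get(str(name_or_path), Path(name_or_path))
    fractions: dict[str, float] = {}
    with open(src, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, frac = line.split()
            fractions[aa] = float(frac)
    total = sum(fractions.values())
    fractions = {aa: v / total for aa, v in fractions.items()}  # tidy rounding
    return CompositionVector(fractions, total_residues=0)


def load_residue_order(path: str | Path | None = None) -> ResidueOrder:
    """Load the display order (default: packaged TopIDP ranking)."""
    src = Path(path) if path is not None else packaged_data_path(
        "residue_order_topidp.txt")
    with open(src, encoding="utf-8") as fh:
        tokens = [t for line in fh if not line.startswith("#")
                  for t in line.split()]
    return ResidueOrder(tuple(tokens), label=src.stem)
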