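"""Whole-protein binary order/disorder classification and CH-CDF quadrants.

Two complementary binary classifiers:

* the charge–hydropathy (CH) plot, a linear discriminant in the plane of
  mean normalized hydropathy ``<H>`` vs mean absolute net charge ``|<R>|``;
  ``dCH`` is the signed vertical (charge-axis) distance of the protein from
  the boundary line, positive on the disordered side;
* CDF analysis, which compares the cumulative distribution of a protein's
  calibrated per-residue disorder scores against a boundary curve; ``dCDF``
  is the mean signed vertical distance at the boundary points, positive on
  the ordered side.

A protein's position in the (dCDF, dCH) plane — CH-CDF phase space — sorts
it into four quadrants: Q1 disordered by CH only, Q2 ordered by both, Q3
disordered by CDF only (putative molten globules / mixed proteins), Q4
disordered by both (extended disorder).

dCH is the *vertical* distance rather than the perpendicular one: this makes
``dCH`` equal to the negated single-window FoldIndex raw value exactly,
which the test-suite uses as a cross-module oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .dataset_io import ProteinRecord, packaged_data_path
from .residue_profiles import CHBoundaryParams, ScoreProfile, load_ch_params

__all__ = [
    "CHPoint",
    "CDFBoundary",
    "CDFCurve",
    "QuadrantPoint",
    "ch_point",
    "cdf_curve",
    "quadrant",
    "load_cdf_boundary",
]


@dataclass(frozen=True)
class CHPoint:
    """A protein's coordinates on the charge–hydropathy plot.

    ``dCH = |<R>| - (slope * <H> - intercept)``; positive = disordered side.
    """

    accession: str
    mean_hydropathy: float
    mean_abs_net_charge: float
    dch: float

    @property
    def disordered(self) -> bool:
        return self.dch > 0


@dataclass(frozen=True)
class CDFBoundary:
    """Order/disorder boundary for CDF analysis: (threshold, fraction) pairs."""

    points: tuple[tuple[float, float], ...]
    source: str = "unnamed"

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("CDF boundary needs at least 3 points")
        thresholds = [t for t, _ in self.points]
        if any(b >= a for a, b in zip(thresholds[1:], thresholds)):
            raise ValueError("boundary thresholds must strictly increase")
        for t, f in self.points:
            if not (0.0 <= t <= 1.0 and 0.0 <= f <= 1.0):
                raise ValueError("boundary points must lie in [0,1]^2")

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.points])


@dataclass(frozen=True)
class CDFCurve:
    """A protein's score CDF evaluated at the boundary thresholds.

    ``F(t)`` = fraction of residues with score <= t (non-decreasing);
    ``dcdf`` = mean of ``F(t) - boundary(t)`` over the boundary points,
    positive on the ordered side.  ``majority_call`` is ordered iff the
    curve lies strictly above the boundary at a strict majority of points —
    near the boundary the sign of ``dcdf`` and the majority call can
    disagree, so both are reported.
    """

    accession: str
    thresholds: np.ndarray
    fractions: np.ndarray
    dcdf: float
    majority_call: Literal["ordered", "disordered"]


@dataclass(frozen=True)
class QuadrantPoint:
    """(dCDF, dCH) coordinates and quadrant call of one protein."""

    accession: str
    x: float  # dCDF
    y: float  # dCH
    quadrant: Literal["Q1", "Q2", "Q3", "Q4"]


def load_cdf_boundary(path: str | Path | None = None) -> CDFBoundary:
    """Load a CDF boundary file (lines ``threshold boundary_fraction``).

    With no path, loads the packaged synthetic default boundary; tests and
    exact reproductions should supply an explicit predictor-matched file.
    """
    src = Path(path) if path is not None else packaged_data_path(
        "cdf_boundary_synthetic.tsv")
    pts = []
    with open(src, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, f = line.split()
            pts.append((float(t), float(f)))
    return CDFBoundary(tuple(pts), source=src.name)


def ch_point(record: ProteinRecord,
             params: CHBoundaryParams | None = None) -> CHPoint:
    """Place a protein on the charge–hydropathy plot.

    ``<H>`` and ``|<R>|`` are computed over the full sequence with ambiguity
    codes excluded; ``dCH > 0`` calls the protein disordered (natively
    unfolded), ``dCH <= 0`` compact.
    """
    if params is None:
        params = load_ch_params()
    hscale = params.hydropathy_scale
    standard = [c for c in record.sequence if c in hscale.values]
    if not standard:
        raise ValueError(
            f"{record.accession}: no standard residues to analyze"
        )
    mean_h = sum(hscale.values[c] for c in standard) / len(standard)
    mean_r = sum(params.charge_map.get(c, 0) for c in standard) / len(standard)
    abs_r = abs(mean_r)
    dch = abs_r - (params.slope * mean_h - params.intercept)
    return CHPoint(record.accession, mean_h, abs_r, dch)


def cdf_curve(profile: ScoreProfile, boundary: CDFBoundary) -> CDFCurve:
    """Evaluate a calibrated profile's score CDF against a boundary."""
    if not profile.calibrated:
        raise ValueError("cdf_curve requires a calibrated profile")
    thresholds = boundary.thresholds
    # F(t): fraction of residues with score <= t (inclusive)
    fractions = (profile.scores[None, :] <= thresholds[:, None]).mean(axis=1)
    diffs = fractions - boundary.fractions
    dcdf = float(diffs.mean())
    n_above = int((diffs > 0).sum())
    call = "ordered" if n_above * 2 > len(thresholds) else "disordered"
    return CDFCurve(profile.accession, thresholds, fractions, dcdf, call)


def quadrant(y_dch: float, x_dcdf: float) -> str:
    """Quadrant of CH-CDF phase space.

    Q1: disordered by CH only (y>0, x>0);  Q2: ordered by both (y<=0, x>0);
    Q3: disordered by CDF only (y<=0, x<=0);  Q4: disordered by both
    (y>0, x<=0).  Exact zeros fall to the ordered side of each axis.
    """
    if not (math.isfinite(y_dch) and math.isfinite(x_dcdf)):
        raise ValueError("quadrant requires finite coordinates")
    if x_dcdf > 0:
        return "Q1" if y_dch > 0 else "Q2"
    return "Q4" if y_dch > 0 else "Q3"


def quadrant_point(accession: str, y_dch: float, x_dcdf: float) -> QuadrantPoint:
    """Bundle coordinates with their quadrant call."""
    return QuadrantPoint(accession, x_dcdf, y_dch, quadrant(y_dch, x_dcdf))
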