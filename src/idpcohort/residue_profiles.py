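"""Per-residue disorder profiles.

Two profile sources are computed natively:

* :func:`windowed_profile` — sliding-window mean of any amino-acid propensity
  scale (e.g. the TopIDP order–disorder scale) over a symmetric window
  (default width 21) that shrinks at the sequence ends;
* :func:`foldindex_profile` — FoldIndex-style unfoldability, the signed
  distance of each 21-residue window from the charge–hydropathy boundary
  line ``|<R>| = slope * <H> - intercept`` (negative raw value = disordered).

Profiles produced by external per-residue predictors (PONDR family, RONN,
IUPred, ...) are imported from their de facto plain-text layout with
:func:`import_score_profile`; they are *calibrated*: scores in [0, 1] with
0.5 the order/disorder threshold.  :func:`binarize`,
:func:`disorder_content` and :func:`long_disordered_regions` turn profiles
into the per-protein quantities the cohort statistics consume.

Ambiguity codes (X, B, Z, U, O) have no scale values; they are excluded from
window means, and a window containing only ambiguity codes falls back to the
whole-sequence mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .dataset_io import (Interval, ProteinRecord, STANDARD_AA,
                         packaged_data_path)

__all__ = [
    "ResidueScale",
    "WindowSpec",
    "CHBoundaryParams",
    "ScoreProfile",
    "DisorderMask",
    "load_scale",
    "load_ch_params",
    "windowed_profile",
    "foldindex_profile",
    "import_score_profile",
    "binarize",
    "disorder_content",
    "long_disordered_regions",
]


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue propensity scale over the 20 standard residues."""

    name: str
    values: dict[str, float]
    declared_range: tuple[float, float] | None = None
    higher_means: Literal["order", "disorder"] = "disorder"

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.values)
        if missing:
            raise ValueError(
                f"scale {self.name!r} missing residues {sorted(missing)}"
            )
        if self.declared_range is not None:
            lo, hi = self.declared_range
            vals = list(self.values.values())
            if min(vals) < lo or max(vals) > hi:
                raise ValueError(
                    f"scale {self.name!r} values escape declared range"
                )

    def normalized(self) -> "ResidueScale":
        """Min–max rescale of the declared range onto [0, 1]."""
        if self.declared_range is None:
            raise ValueError(f"scale {self.name!r} has no declared range")
        lo, hi = self.declared_range
        return ResidueScale(
            name=f"{self.name}_norm",
            values={aa: (v - lo) / (hi - lo) for aa, v in self.values.items()},
            declared_range=(0.0, 1.0),
            higher_means=self.higher_means,
        )


@dataclass(frozen=True)
class WindowSpec:
    """Odd-width sliding window; shrinks (is clipped) at sequence ends."""

    width: int = 21
    edge_policy: Literal["shrink"] = "shrink"

    def __post_init__(self) -> None:
        if self.width < 3 or self.width % 2 == 0:
            raise ValueError("window width must be odd and >= 3")


def _default_charge_map() -> dict[str, int]:
    return {"D": -1, "E": -1, "K": 1, "R": 1}


@dataclass(frozen=True)
class CHBoundaryParams:
    """Charge–hydropathy boundary line and the scales it is defined over.

    The boundary is ``|<R>| = slope * <H> - intercept`` with ``<H>`` the mean
    hydropathy on a [0, 1] normalized scale and ``<R>`` the mean net charge
    per residue.
    """

    slope: float = 2.785
    intercept: float = 1.151
    hydropathy_scale: ResidueScale | None = None
    charge_map: dict[str, int] = field(default_factory=_default_charge_map)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        scale = self.hydropathy_scale or load_scale("kyte_doolittle").normalized()
        if scale.declared_range != (0.0, 1.0):
            scale = scale.normalized()
        object.__setattr__(self, "hydropathy_scale", scale)


@dataclass(frozen=True)
class ScoreProfile:
    """Per-residue scores for one protein from a named predictor or scale.

    ``calibrated`` is True iff scores live in [0, 1] with 0.5 as the
    order/disorder threshold (the convention of the imported predictors).
    """

    accession: str
    predictor: str
    scores: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores",
                           np.asarray(self.scores, dtype=float))
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if self.calibrated and (
                self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("calibrated profile must lie within [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class DisorderMask:
    """Per-residue boolean disorder labels (True = disordered)."""

    accession: str
    labels: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels",
                           np.asarray(self.labels, dtype=bool))
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")

    def __len__(self) -> int:
        return self.labels.size


_SCALES_CACHE: dict[str, ResidueScale] = {}


def load_scale(name: str, path: str | Path | None = None) -> ResidueScale:
    """Load a named scale from the packaged (or a user) scales YAML file."""
    if path is None and name in _SCALES_CACHE:
        return _SCALES_CACHE[name]
    src = Path(path) if path is not None else packaged_data_path("scales.yaml")
    with open(src, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if name not in data:
        raise KeyError(f"scale {name!r} not in {src}")
    entry = data[name]
    rng = entry.get("declared_range")
    scale = ResidueScale(
        name=name,
        values={str(k): float(v) for k, v in entry["values"].items()},
        declared_range=tuple(rng) if rng else None,
        higher_means=entry.get("higher_means", "disorder"),
    )
    if path is None:
        _SCALES_CACHE[name] = scale
    return scale


def load_ch_params(path: str | Path | None = None) -> CHBoundaryParams:
    """Charge–hydropathy boundary parameters from the packaged config."""
    src = Path(path) if path is not None else packaged_data_path(
        "ch_boundary.yaml")
    with open(src, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    charge = {aa: -1 for aa in cfg["charge"]["negative"]}
    charge.update({aa: 1 for aa in cfg["charge"]["positive"]})
    scale = load_scale(cfg["hydropathy_scale"]).normalized()
    return CHBoundaryParams(slope=float(cfg["slope"]),
                            intercept=float(cfg["intercept"]),
                            hydropathy_scale=scale,
                            charge_map=charge)


def _window_bounds(n: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive-exclusive 0-based window bounds per position.

    Windows are clipped at the ends; a sequence shorter than the window
    width uses the whole sequence at every position.
    """
    half = width // 2
    idx = np.arange(n)
    if n < width:
        return np.zeros(n, dtype=int), np.full(n, n, dtype=int)
    return np.maximum(idx - half, 0), np.minimum(idx + half + 1, n)


def _windowed_mean(values: np.ndarray, present: np.ndarray,
                   width: int) -> np.ndarray:
    """Mean of ``values`` over clipped windows, counting only ``present``
    positions; windows with no present residue get the global present mean."""
    n = values.size
    lo, hi = _window_bounds(n, width)
    vals = np.where(present, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(present.astype(int))])
    wsum = csum[hi] - csum[lo]
    wcnt = ccnt[hi] - ccnt[lo]
    if not present.any():
        raise ValueError("sequence contains no standard residues")
    global_mean = vals.sum() / present.sum()
    out = np.full(n, global_mean)
    nz = wcnt > 0
    out[nz] = wsum[nz] / wcnt[nz]
    return out


def windowed_profile(record: ProteinRecord, scale: ResidueScale,
                     window: WindowSpec = WindowSpec()) -> ScoreProfile:
    """Sliding-window mean of a propensity scale along the sequence.

    The score at position *i* is the mean scale value over the standard
    residues in the window centered at *i*; ambiguity codes are skipped, and
    a window consisting only of ambiguity codes falls back to the
    whole-sequence mean.  The profile is calibrated only if the scale's
    declared range is exactly [0, 1].
    """
    seq = record.sequence
    present = np.array([c in scale.values for c in seq])
    values = np.array([scale.values.get(c, 0.0) for c in seq])
    scores = _windowed_mean(values, present, window.width)
    calibrated = scale.declared_range == (0.0, 1.0)
    return ScoreProfile(record.accession, scale.name, scores, calibrated)


def foldindex_profile(
    record: ProteinRecord,
    params: CHBoundaryParams = None,
    window: WindowSpec = WindowSpec(),
) -> tuple[ScoreProfile, DisorderMask]:
    """FoldIndex-style windowed unfoldability.

    The raw value at position *i* is ``slope * <H>_w - |<R>_w| - intercept``
    over the window *w* centered at *i* (mean normalized hydropathy, mean net
    charge per residue); negative raw values indicate disorder.  The returned
    profile stores the *negated* raw value so that higher = more disordered
    (uncalibrated); the companion mask marks positions with raw value < 0.
    """
    if params is None:
        params = load_ch_params()
    seq = record.sequence
    hscale = params.hydropathy_scale
    present = np.array([c in hscale.values for c in seq])
    hvals = np.array([hscale.values.get(c, 0.0) for c in seq])
    cvals = np.array([float(params.charge_map.get(c, 0)) for c in seq])
    mean_h = _windowed_mean(hvals, present, window.width)
    mean_r = _windowed_mean(cvals, present, window.width)
    raw = params.slope * mean_h - np.abs(mean_r) - params.intercept
    profile = ScoreProfile(record.accession, "foldindex", -raw,
                           calibrated=False)
    mask = DisorderMask(record.accession, raw < 0, threshold=0.0)
    return profile, mask


def import_score_profile(path: str | Path, expected_length: int,
                         predictor: str | None = None,
                         accession: str | None = None) -> ScoreProfile:
    """Import a calibrated per-residue score file.

    Format: whitespace-delimited lines ``index residue score`` (1-based, one
    line per residue); blank lines and ``#`` comments are ignored.  Scores
    must lie in [0, 1]; the residue count must equal ``expected_length``.
    """
    path = Path(path)
    scores: list[float] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected "
                                 "'index residue score'")
            score = float(parts[2])
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: score {score} outside [0, 1]"
                )
            scores.append(score)
    if len(scores) != expected_length:
        raise ValueError(
            f"{path}: {len(scores)} scores but expected {expected_length}"
        )
    return ScoreProfile(
        accession=accession or path.stem,
        predictor=predictor or "imported",
        scores=np.array(scores),
        calibrated=True,
    )


def binarize(profile: ScoreProfile, threshold: float = 0.5) -> DisorderMask:
    """Threshold a calibrated profile: label disordered iff score >= threshold.

    The threshold itself counts as disordered (the convention of the
    imported predictor family).  Uncalibrated profiles are rejected —
    FoldIndex-style profiles come with their own boundary-sign mask.
    """
    if not profile.calibrated:
        raise ValueError(
            "binarize requires a calibrated profile; foldindex_profile "
            "returns its own DisorderMask"
        )
    return DisorderMask(profile.accession, profile.scores >= threshold,
                        threshold)


def disorder_content(mask: DisorderMask) -> float:
    """Fraction of residues labelled disordered."""
    if len(mask) == 0:
        raise ValueError("empty mask")
    return float(mask.labels.mean())


def long_disordered_regions(mask: DisorderMask,
                            min_len: int = 30) -> list[Interval]:
    """Maximal runs of disordered labels of length >= ``min_len``.

    Returned as sorted 1-based inclusive intervals; runs are maximal, hence
    disjoint and separated by at least one ordered residue.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    lab = mask.labels
    if lab.size == 0:
        return []
    padded = np.concatenate([[False], lab, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)   # 0-based run starts
    ends = np.flatnonzero(d == -1)    # 0-based exclusive run ends
    return [Interval(int(s) + 1, int(e))
            for s, e in zip(starts, ends) if e - s >= min_len]
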