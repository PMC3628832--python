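"""Synthetic protein cohorts with known order/disorder ground truth.

Each protein is generated from a two-state (ordered/disordered) Markov chain
along the sequence: segment lengths are geometric with means ``seg_ordered``
and ``seg_disordered`` (per-residue switch probabilities ``1/Lo`` and
``1/Ld``), giving a stationary disordered fraction
``theta = Ld / (Lo + Ld)``.  Residues are drawn from a state-dependent
composition (by default the packaged ordered/disordered reference
compositions, so composition profiling of the generated states reproduces
the expected enrichment pattern), and a calibrated per-residue score profile
is emitted as the moving-average-smoothed state indicator plus Gaussian
noise, clipped to [0, 1].

With zero noise and no smoothing the emitted profile equals the true label
indicator exactly, which gives the pipeline a noiseless identity to test
against; clipping slightly biases scores near 0 and 1 at high noise, which
is why recovery tests quote tolerances rather than exact equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binary_classifiers import quadrant_point
from .cohort_stats import CohortSummary, ContentClassScheme, cohort_summary
from .composition_profiler import CompositionVector, load_composition
from .dataset_io import AnnotationRow, ProteinRecord, STANDARD_AA
from .residue_profiles import DisorderMask, ScoreProfile

__all__ = [
    "SyntheticSpec",
    "SyntheticProtein",
    "sample_protein",
    "sample_cohort",
    "true_statistics",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a synthetic cohort.

    ``theta`` must equal the stationary disordered fraction
    ``seg_disordered / (seg_ordered + seg_disordered)`` implied by the mean
    segment lengths; use :meth:`from_theta` to derive a consistent spec.
    ``theta`` of exactly 0 or 1 pins every residue to one state.
    """

    n_proteins: int = 100
    length_min: int = 100
    length_max: int = 500
    theta: float = 0.5
    seg_ordered: float = 40.0
    seg_disordered: float = 40.0
    noise_sd: float = 0.1
    smooth_window: int = 1
    seed: int = 0
    ordered_composition: CompositionVector | None = None
    disordered_composition: CompositionVector | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.length_min < 1:
            raise ValueError("need n_proteins >= 1 and length_min >= 1")
        if self.length_max < self.length_min:
            raise ValueError("length_max < length_min")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if min(self.seg_ordered, self.seg_disordered) < 1:
            raise ValueError("mean segment lengths must be >= 1")
        if 0.0 < self.theta < 1.0:
            implied = self.seg_disordered / (self.seg_ordered
                                             + self.seg_disordered)
            if abs(implied - self.theta) > 1e-9:
                raise ValueError(
                    f"theta={self.theta} inconsistent with segment lengths "
                    f"(implied {implied:.6f}); use SyntheticSpec.from_theta"
                )
        if self.ordered_composition is None:
            object.__setattr__(self, "ordered_composition",
                               load_composition("ordered"))
        if self.disordered_composition is None:
            object.__setattr__(self, "disordered_composition",
                               load_composition("disordered"))

    @classmethod
    def from_theta(cls, theta: float, seg_disordered: float = 40.0,
                   **kwargs) -> "SyntheticSpec":
        """Spec with ``seg_ordered`` derived from theta and ``seg_disordered``."""
        if not 0.0 < theta < 1.0:
            return cls(theta=theta, seg_disordered=seg_disordered, **kwargs)
        seg_ordered = seg_disordered * (1.0 - theta) / theta
        return cls(theta=theta, seg_ordered=seg_ordered,
                   seg_disordered=seg_disordered, **kwargs)


@dataclass(frozen=True)
class SyntheticProtein:
    """A generated sequence with its truth labels and emitted score profile."""

    record: ProteinRecord
    labels: np.ndarray          # True = disordered (ground truth)
    profile: ScoreProfile       # emitted noisy calibrated scores

    @property
    def true_mask(self) -> DisorderMask:
        return DisorderMask(self.record.accession, self.labels, threshold=0.5)

    @property
    def true_content(self) -> float:
        return float(self.labels.mean())


def _sample_states(n: int, spec: SyntheticSpec,
                   rng: np.random.Generator) -> np.ndarray:
    if spec.theta == 0.0:
        return np.zeros(n, dtype=bool)
    if spec.theta == 1.0:
        return np.ones(n, dtype=bool)
    p_od = 1.0 / spec.seg_ordered      # ordered -> disordered switch prob
    p_do = 1.0 / spec.seg_disordered   # disordered -> ordered switch prob
    states = np.empty(n, dtype=bool)
    state = bool(rng.random() < spec.theta)  # stationary initial state
    u = rng.random(n)
    for i in range(n):
        states[i] = state
        if state:
            state = not (u[i] < p_do)
        else:
            state = u[i] < p_od
    return states


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(x.astype(float))])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def sample_protein(spec: SyntheticSpec, rng: np.random.Generator,
                   accession: str = "SYN0001") -> SyntheticProtein:
    """Draw one synthetic protein: states, residues, emitted scores."""
    n = int(rng.integers(spec.length_min, spec.length_max + 1))
    labels = _sample_states(n, spec, rng)
    aa = np.array(list(STANDARD_AA))
    p_ord = np.array([spec.ordered_composition.fractions[a] for a in aa])
    p_dis = np.array([spec.disordered_composition.fractions[a] for a in aa])
    seq = np.empty(n, dtype="<U1")
    n_dis = int(labels.sum())
    if n_dis < n:
        seq[~labels] = rng.choice(aa, size=n - n_dis, p=p_ord)
    if n_dis:
        seq[labels] = rng.choice(aa, size=n_dis, p=p_dis)
    scores = _smooth(labels, spec.smooth_window)
    if spec.noise_sd > 0:
        scores = scores + rng.normal(0.0, spec.noise_sd, size=n)
    scores = np.clip(scores, 0.0, 1.0)
    record = ProteinRecord(accession, f"synthetic {accession}",
                           "".join(seq))
    profile = ScoreProfile(accession, "synthetic", scores, calibrated=True)
    return SyntheticProtein(record, labels, profile)


def sample_cohort(spec: SyntheticSpec) -> list[SyntheticProtein]:
    """Draw ``spec.n_proteins`` independent proteins; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    return [sample_protein(spec, rng, accession=f"SYN{i + 1:04d}")
            for i in range(spec.n_proteins)]


def _rows_from_cohort(cohort: Sequence[SyntheticProtein]) -> list[AnnotationRow]:
    # minimal annotation rows so cohort_summary can aggregate a synthetic set
    rows = []
    for sp in cohort:
        rows.append(AnnotationRow(
            accession=sp.record.accession,
            protein_name=sp.record.name,
            gene_name="",
            complex_group="Other",
            mw_kda=0.11 * sp.record.length,  # ~average residue mass in kDa
            length=sp.record.length,
            content_scores={"fit": sp.true_content, "vlxt": sp.true_content,
                            "foldindex": sp.true_content,
                            "ronn": sp.true_content},
        ))
    return rows


def true_statistics(
    cohort: Sequence[SyntheticProtein],
    scheme: ContentClassScheme = ContentClassScheme(),
    min_len: int = 30,
) -> CohortSummary:
    """Cohort statistics computed from the *true* labels.

    The same aggregation as the prediction pipeline, but with the planted
    state labels in place of binarized predictions — this is the recovery
    target the pipeline's estimates are compared against.  CH-CDF points are
    derived from the generated sequences (CH axis) and the pure label
    indicator profiles (CDF axis).
    """
    if not cohort:
        raise ValueError("empty cohort")
    from .binary_classifiers import cdf_curve, ch_point, load_cdf_boundary

    rows = _rows_from_cohort(cohort)
    masks = {sp.record.accession: sp.true_mask for sp in cohort}
    boundary = load_cdf_boundary()
    points = []
    for sp in cohort:
        chp = ch_point(sp.record)
        ind = ScoreProfile(sp.record.accession, "truth",
                           sp.labels.astype(float), calibrated=True)
        cdf = cdf_curve(ind, boundary)
        points.append(quadrant_point(sp.record.accession, chp.dch, cdf.dcdf))
    return cohort_summary(rows, masks=masks, points=points, scheme=scheme,
                          min_len=min_len)
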