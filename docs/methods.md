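# Methods

## Scope and data model

`idpcohort` analyzes a *cohort* of proteins for intrinsic disorder at three
levels: per residue (score profiles), per protein (binary order/disorder
calls, disorder content, long disordered regions), and per cohort
(composition profiles, content classes, quadrant fractions, binding-site
carrier statistics).  Residue coordinates are 1-based inclusive everywhere
a user sees them — the convention of the printed interval annotations
("15-32") — and converted to 0-based indices only at array boundaries.

Neural-network disorder predictors (PONDR family, RONN, IUPred, the α-MoRF
stacked predictor, ANCHOR) are *not* reimplemented: their per-residue
outputs enter as imported score files in the de facto plain-text layout
(`index residue score`, 1-based), and their interval predictions enter
through the annotation table.  What the package computes natively are the
scale-based profiles (windowed propensity means, FoldIndex), the binary
classifiers operating on sequences and imported scores, and all the
aggregation on top.

## Per-residue profiles

**Windowed scale profile.** The score at position *i* is the mean scale
value over a symmetric window of odd width *w* (default 21, the width the
window-based disorder methods standardized on) centered at *i*.  Windows
are clipped at the sequence ends so every residue receives a score; a
sequence shorter than the window is scored by its whole-sequence mean at
every position.  Ambiguity codes (X, B, Z, U, O) have no scale values and
are excluded from window means; a window containing only ambiguity codes
falls back to the whole-sequence mean.  Means are computed with cumulative
sums, so profiling is O(n) per protein.

**FoldIndex-style unfoldability.** The raw value at position *i* is

    raw(i) = 2.785 · ⟨H⟩_w − |⟨R⟩_w| − 1.151

over the window *w*: ⟨H⟩ is the mean Kyte–Doolittle hydropathy min-max
normalized to [0, 1] via (v + 4.5)/9, and ⟨R⟩ the mean net charge per
residue (D, E → −1; K, R → +1, others 0; no pH model).  Negative raw
values indicate disorder.  The returned profile stores the negated value
so that, like every other profile, higher means more disordered; the
companion boolean mask (raw < 0) carries the binary call.  Slope,
intercept, scale values and charge assignments live in editable config
files (`data/ch_boundary.yaml`, `data/scales.yaml`), so published variants
of the constants can be swapped in without code changes.

**Binarization.** Calibrated profiles (scores in [0, 1], threshold 0.5)
are thresholded with `score >= threshold` — the tie at the threshold
counts as disordered, the convention of the imported predictor family.
Lowering the threshold can only grow the disordered set, so disorder
content is monotone in the threshold (property-tested).  Disorder content
is the fraction of disordered labels; long disordered regions are maximal
runs of ≥ `min_len` (default 30) disordered residues.

## Whole-protein binary classifiers

**CH-plot.**  A protein is a point (⟨H⟩, |⟨R⟩|) computed over its full
sequence (ambiguity codes excluded).  The boundary line is
`|⟨R⟩| = 2.785·⟨H⟩ − 1.151`; `dCH` is the *vertical* signed distance
`|⟨R⟩| − (2.785·⟨H⟩ − 1.151)`, positive on the disordered (high-charge,
low-hydropathy) side.  Vertical rather than perpendicular distance was a
genuinely open choice; vertical was adopted because it makes `dCH` equal
to the negated whole-sequence FoldIndex raw value *exactly*, an algebraic
identity the test suite exploits as a free cross-module oracle (tolerance
1e−12 on random sequences).

**CDF analysis.**  For a calibrated profile, `F(t)` = fraction of residues
with score ≤ *t* (inclusive), evaluated at the boundary's threshold
points.  `dCDF` is the unweighted mean of `F(t) − boundary(t)` over the
boundary points; positive means the curve lies above the boundary, i.e.
most residues have low disorder scores — the ordered side.  The binary
call uses a strict majority of boundary points rather than the sign of
`dCDF`; the two can disagree for curves that cross the boundary, so both
are reported.  The packaged default boundary
(`data/cdf_boundary_synthetic.tsv`) is a constructed monotone 7-point
boundary labelled synthetic: published predictor-specific boundary tables
are predictor-calibrated, and which one a given survey used is generally
configurable, so the boundary is a config file and every test needing
exact numbers constructs its own explicit boundary.

**CH-CDF quadrants.**  With `x = dCDF`, `y = dCH`: Q1 (y>0, x>0), Q2
(y≤0, x>0), Q3 (y≤0, x≤0), Q4 (y>0, x≤0).  Exact zeros fall to the
ordered side of each axis — (0, 0) is Q3 — a documented tie rule; the
convention for zeros is not standardized anywhere.

## Composition profiling

The pooled composition of a query set is compared with a reference set
residue by residue via the fractional difference
`(C_X − C_ref)/C_ref`: −1 means the residue is absent from the query, 0
means identical frequency.  Residues with zero reference frequency yield
an undefined (NaN) entry with a warning, never ±∞.  The sum rule
`Σ_X C_ref(X)·(1 + diff(X)) = 1` holds by construction and is asserted to
1e−9.  Confidence intervals are percentile bootstrap (default 10 000
replicates) resampling *proteins* with replacement within the query set —
the cohort, not the residue pool, is the sampling unit, so proteins of
different lengths contribute their natural weight.  Whether the original
error bars were bootstrap or analytic is not documented; bootstrap was
adopted.  Residue display order is the TopIDP ranking (order-promoting W
through disorder-promoting P), shipped as a config permutation.

The packaged reference compositions (`composition_ordered_synthetic.tsv`,
`composition_disordered_synthetic.tsv`) are *constructed stand-ins*, not
published tables: plausible globular frequencies with a monotone
enrichment gradient along the disorder-propensity ranking.  They support
the qualitative directional tests (disordered cohorts enriched in
disorder-promoting residues, depleted in order-promoting ones) and the
synthetic generator's state compositions; quantitative comparison against
a specific published reference requires dropping in that reference's
composition file.

## Cohort statistics

Disorder-content classes use cutoffs 0.10 and 0.30 with strict
inequalities on the outer classes; values exactly at a cutoff belong to
the middle class (the published inequalities leave the boundary open).
Long-region prevalence is the percentage of proteins with ≥ 1 disordered
run of ≥ 30 residues, reported to one decimal.  Interval (MoRF/AIBS)
statistics count only intervals that validated against the protein length;
malformed tokens — the packaged table prints two, "1-0" (Ntr2) and
"55-52" (Prp16) — are flagged and reported in the summary footer, never
silently dropped and never counted.  Carrier percentages are rounded
half-away-from-zero to the integer precision the survey literature uses.

On the packaged 109-protein table these statistics reproduce the survey's
countable results: 67 MoRF carriers (61 %), 77 AIBS carriers (71 %), and
the per-protein MoRF counts of the highlighted proteins (Prp3 7, Spp381 6,
Yju2 5, Snu66 11).  Quantities that depend on proprietary per-residue
predictor output (long-region prevalence of the real cohort, its CH-CDF
quadrant fractions, its content-class split) are computed by the same
machinery from whatever profiles the user supplies but have no packaged
ground truth.

## Synthetic cohort generator

Each protein's order/disorder architecture is a two-state Markov chain
along the sequence: per-residue switch probabilities 1/Lo (ordered →
disordered) and 1/Ld (disordered → ordered) give geometric segment lengths
with means Lo and Ld and a stationary disordered fraction
θ = Ld/(Lo + Ld); the initial state is drawn from the stationary
distribution, so the expected disordered fraction is θ at every length.
The spec validates θ against the segment means (use
`SyntheticSpec.from_theta` to derive Lo).  Defaults: 100 proteins, lengths
uniform on [100, 500], θ = 0.5, Lo = Ld = 40 (segment scale chosen so that
runs comfortably span the 30-residue long-region cutoff without making
whole proteins single-state), noise σ = 0.1, no smoothing.  Residues are
drawn from state-dependent compositions (the packaged ordered/disordered
references by default), so composition profiling of the generated states
reproduces the planted enrichment pattern.  Emitted scores are the
moving-average-smoothed state indicator plus Gaussian noise, clipped to
[0, 1].

Clipping biases scores near the extremes at large σ (a clipped Gaussian
centred at 0 has positive mean), which is why recovery tests quote
tolerances; with σ = 0 and no smoothing the emitted profile equals the
truth indicator exactly and the pipeline must recover every statistic
identically (tested).  At the test conditions (n = 200, L = 500, θ = 0.5,
σ = 0.1) mean binarized content is unbiased to < 0.01 because threshold
crossings up and down are symmetric away from the clip boundaries.

What the generator does *not* emulate: domain architecture, sequence
evolution and homology, predictor-specific error correlation along the
sequence (noise is i.i.d. per residue), or length–disorder correlation.
Passing recovery tests therefore demonstrates the pipeline's correctness
and calibration under the stated generative model, not predictor accuracy
on real proteins.

## Numerical and interface choices

- All window and CDF operations are exact counting/averaging; no
  interpolation anywhere, so oracle tests assert exact equality.
- All randomness (generator, bootstrap) flows through
  `numpy.random.default_rng(seed)`; identical seeds give byte-identical
  cohorts, CIs and written reports.
- The annotation reader defaults to lenient validation because the
  packaged printed table contains malformed interval tokens; strict mode
  exists for curated new data and raises on the first violation or
  duplicate accession.
- Report files are written with sorted keys and fixed float formatting so
  reruns are byte-identical.
- Problem sizes in the test suite (cohorts of 30–200 proteins of length
  300–1000) were chosen as the smallest sizes at which the law-of-large-
  numbers tolerances quoted above are comfortably stable.

## Known limitations

- The CH boundary constants and the Kyte–Doolittle normalization are the
  widely used published values but ship as editable config; exact
  agreement with any specific web-server implementation (rounding of scale
  values, terminal-window policy) is not guaranteed.
- The per-protein FoldIndex contents printed in annotation tables of this
  kind are not exactly reproducible from sequence alone (implementations
  differ in edge handling); the packaged table's per-predictor content
  columns are treated as data, not as targets for the native FoldIndex.
- AIBS/MoRF intervals are consumed as given; the package does not judge
  their biological validity beyond coordinate validation.
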