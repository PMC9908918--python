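# Methods

This note records the models, numerical choices and limitations behind
`earmorph`, in the order data flow through the pipeline.

## Landmark data and units

A specimen is an ordered 3D polyline (mm) following the outermost wall of
the bony cochlear spiral from the round window to the apex, plus a closed
outline around the oval window.  The first two points are anatomical
landmarks at the superior and inferior margins of the round window; the
remainder are semilandmarks.  Units are fixed at parse time: kHz for
frequency, dB SPL for thresholds, mm for lengths, g for body mass.
Parsing is strict — malformed lines, non-finite coordinates,
non-increasing frequency grids and unknown method tags are errors, never
silently coerced.  Left-side specimens are mirrored (x negated) before
any alignment so all configurations share one chirality.

## Resampling and the 130-point configuration

Semilandmarks are resampled to equal consecutive *chord* lengths along
the digitized polyline, endpoints pinned.  Uniform arc-length placement
alone leaves chords unequal wherever the polyline bends, so the placement
is refined iteratively (remap positions through the cumulative chord
function) until chords agree to relative 1e-9, capped at 100 iterations.
A configuration is [LM1, LM2, 127 semilandmarks strictly between LM2 and
apex, apex] — 130 points.  Rebuilding a configuration from itself moves
no point by more than 1e-9 (fixed point).

## Cochlear metrics

* **CL** — polyline arc length.  The LM1–LM2 round-window segment is
  included by default (`include_rw_segment`); on synthetic data this adds
  a constant ≈1.6·ρ0 relative to the spiral-only truth, which is
  irrelevant for regressions on log CL.
* **Spiral axis** — initial estimate: mean cross product of consecutive
  segment pairs.  Refinement: the least-squares plane of the basal-turn
  points is systematically tilted for tall cochleae because the curve
  rises axially across the turn, so we iterate: compute winding under the
  current axis, regress the axial coordinate on winding, subtract the
  fitted rise, refit the plane to the detrended points (≤8 iterations,
  early exit at 1e-14).  For a noiseless helix the detrended basal turn
  is exactly planar, so the axis is recovered to machine precision.
* **NT** — total winding about the axis, measured as the accumulated
  rotation of consecutive projected chord directions plus half of the
  first and last rotation steps (the half-chords a discrete tangent
  misses at each end).  For a uniformly sampled logarithmic spiral this
  estimator is exact; measuring rotation of chord *directions* rather
  than of radius vectors about a centre point removes the sensitivity to
  centre placement that otherwise biases the fractional part of the
  winding.  NT is quantised as floor(10·turns + 0.01)/10: sectors count
  only when fully crossed, with a 1e-3-turn snap so that a winding
  sitting exactly on a sector boundary is not lost to roundoff.  The
  snap was sized from the discretisation-error analysis of the chord
  estimator (worst observed |error| ≈ 2e-3 turns with basal-turn
  undulation, well under the 0.1-turn sector).  `rounding="nearest"` is
  available; counting only fully crossed sectors is the default because
  the visual sector-counting protocol it reproduces does not credit
  partial sectors.
* **CW** — points whose cumulative winding is ≤ 2π from the start form
  the basal turn; CW is the maximum pairwise distance among their
  projections onto the plane perpendicular to the axis.  This is a
  reproducible computational analogue of measuring a single μCT slice
  just below the round window; the two agree in ordering but not
  numerically, and basal-turn membership at the 2π boundary makes CW
  definitional to ~0.5%.
* **OWA** — least-squares plane fit (SVD), projection, shoelace area.
  Self-intersecting projections warn and return the absolute area.
* **ACS / CSR** — the five cross-section areas at 1/5…5/5 of
  configuration arc length (areas are inputs; the pipeline never
  re-segments images): ACS is their mean, CSR = area(1/5)/area(5/5).
* **CS** — sqrt of summed squared distances to the centroid.

## Superimposition and shape spaces

GPA: centre, scale to unit centroid size, rotate each configuration to
the running consensus by the optimal SVD rotation with reflections
excluded (sides were mirrored upstream), update the consensus, iterate to
1e-10 or 100 iterations.  All specimens are aligned jointly in one GPA
and species consensus shapes are averaged afterwards ("joint" order,
`gpa_order` switch exposes consensus-first); joint alignment keeps every
specimen in a single rotational frame.  No semilandmark sliding and no
tangent-space projection: semilandmarks are equidistant by construction
and shape variation is small, so PCA runs on Procrustes coordinates
directly.

PCA signs are fixed by making the largest-magnitude loading entry
positive.  Phylogenetic PCA uses the GLS mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and
eigenvectors of R = (X−1aᵀ)ᵀC⁻¹(X−1aᵀ)/(n−1); scores are (X−1aᵀ)V.  On a
star tree pPCA reduces to PCA.

## Audiometry

All interpolation is piecewise-linear in (log₂ frequency, dB): octave
arithmetic is linear there and audiograms are conventionally read on
log-frequency axes.

* **Cut-offs** at the 60 dB SPL criterion.  If a flank crosses the
  criterion within the tested range, the crossing nearest the audiogram
  minimum is returned (non-monotone flanks can cross twice).  Otherwise,
  when the terminal tested threshold is ≥ 45 dB SPL the line through the
  last two tested points is extended to the criterion; below that floor
  the cut-off is missing.  The slope source (last two tested points) is
  the package's choice; the trigger threshold is part of the extraction
  rule.
* **Averages** over half-octave ladders f_lo·2^{0,0.5,…} with f_hi
  appended when off-ladder; grid points beyond the tested range use the
  terminal-segment extension.  MS is computed as the LFC→HFC average on
  the same ladder (its grid is otherwise unspecified; configurable).
  ASL anchors at LFC whenever LFC is available, including when
  extrapolated.
* **Characteristic frequencies** are local threshold minima with
  prominence ≥ 2 dB (scipy's peak prominence equals the smaller rise to
  the enclosing maxima).  Two or more retained dips: CF1 = lowest dip
  frequency, CF2 = highest, PS = the lower of their thresholds; one dip:
  CF1 = CF2.  The 2 dB rule quantifies "two peaks"; no numeric criterion
  exists in the audiometric convention this follows.
* **ABR correction**: factors = mean over two reference species of
  (behavioral − ABR) threshold at 11 frequencies on a half-octave ladder
  spanning 1–32 kHz (the count and range are fixed; the ladder placement
  is the package's choice).  Corrected = ABR + factor, interpolated
  log₂-linearly, nearest factor outside the grid.  With both reference
  species sharing the generating offset the correction cancels exactly.

## Comparative statistics

Brownian motion only — no Pagel's λ, OU or other branch-length
transforms.  C[i,j] is the shared root-to-MRCA path length; species order
is sorted tip labels everywhere.

* **PGLS** by Cholesky whitening; R² is defined against the GLS
  (phylogenetic) mean in whitened space and reduces to classical R² on
  star trees.  Both per-coefficient t tests and the joint F test are
  reported, since either may be meant by a reported regression p.
  Designs with condition number > 1e12 are rejected naming the columns.
* **K / Kmult**: K = [(x−â)ᵀ(x−â)/(x−â)ᵀC⁻¹(x−â)] ÷
  [(tr C − n/(1ᵀC⁻¹1))/(n−1)]; Kmult applies the same ratio with squared
  norms summed over trait columns and equals K for one column.
  Permutation p-values shuffle tips, 999 permutations by default, with
  the (1 + exceedances)/(n_perm + 1) correction; seeds are logged.
* **Ancestral states**: conditional expectation of the joint
  tip-plus-node Gaussian with the GLS mean plugged in for the root;
  the root estimate therefore equals the GLS mean identically.
  Variances are the conditional variance plus propagated root-mean
  uncertainty, scaled by the ML rate estimate.
* **Mann–Whitney U**: exact enumeration of all label assignments for
  n ≤ 12 (midranks for ties; two-sided p = 2·min(tails) capped at 1),
  tie-corrected normal approximation otherwise.

Table-style regression grids use PC scores as predictors of a univariate
response (multiple regression, one R² per cell), with listwise deletion
per cell and the effective n reported; cells with fewer than
max(8, p + 3) species are NA.  Frequencies (LFC, HFC, CF1, CF2) are
regressed in log₂ units; all morphological measures except CSR are
log₁₀-transformed.  Group fits run overall, within each labelled group,
and with the two coiled-rodent groups pooled.  Outlier exclusions are
config-listed per hearing variable, never silent.

## Synthetic worlds

The generator defines the study conditions; its defaults emulate a
33-species sample with 2 specimens per species (the modal sampling of
comparable studies) on a pure-birth ultrametric tree rescaled to a 75 Myr
root (a Euarchontoglires-scale depth).

* **Geometry**: conical-exponential spiral x = r0·e^{−ks}cos(2πTs),
  y = r0·e^{−ks}sin(2πTs), z = Hs, s ∈ [0,1], chosen because four
  interpretable parameters span flat/wide to tall/coiled cochleae with
  closed-form truth for every metric (arc length by quadrature, winding
  = 2πT, tube area π(ρ0(1−cs))², oval window an ellipse).  A basal-turn
  undulation u·sin(2πTs) for s ≤ 1/T completes one full sine period, so
  the curve stays continuous at the basal-turn boundary; its amplitude
  is a free stand-in for the undulating basal morphology seen in real
  wide cochleae, which is not quantified anywhere.
* **Trait evolution**: r0, H, ρ0 evolve as BM on the log scale
  (positivity); T, k, c, u evolve additively with hard lower clips, so
  that a clade shift in T produces an additive between-clade difference
  in turns.  Clade shifts are applied at the stem of named clades; the
  default shifts give one "tower" clade (+0.9 turns, taller) and one
  wide clade (enlarged basal radius, fewer turns).  Rates are sized so
  tip s.d. over the tree depth is ≈ 0.4 turns and ≈ 15–20% in the size
  parameters — within-group spread comparable to the between-group
  shifts.
* **Audiograms**: lower envelopes of one (V) or two (W) parabolas in
  (log₂ f, dB) anchored to cross 60 dB SPL exactly at the true cut-offs;
  the V vertex depth is solved so the curve passes through (1 kHz,
  SPL1_true).  Hearing truth comes from a linear linkage on (log₁₀ CL,
  NT, log₁₀ OWA, log₁₀ CW) with residual s.d. 0.25 octaves on the
  cut-offs and 2.5 dB on SPL1 — effect sizes that put the recovered
  PGLS R² in the 0.3–0.8 range reported for real cochlear data.
  Digitization noise defaults to 0.01 mm per coordinate and 1 dB per
  threshold.
* **ABR variants**: positive offset 9 dB above 4 kHz rising to 18 dB at
  and below 1 kHz — electrophysiological thresholds are systematically
  less sensitive than behavioral ones, most strongly at low frequencies.
  Two reference species carry both record types (the correction-factor
  source); four species are published as ABR-only.
* **Seeding**: one root seed expands through a fixed
  `numpy.random.SeedSequence` spawn order; regeneration and re-writing
  of a world from (config, seed) are bit-identical.

What the generator does **not** emulate: allometric scaling laws beyond
the stated linkage, bone texture or middle-ear structures, measurement
correlation between specimens of one species, non-Brownian evolution,
and literature audiograms' heterogeneous frequency grids.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every failure mode of museum data.

## Problem sizes and calibration checks

The test suite exercises: Monte-Carlo BM covariance at 5 000–10 000
replicates (3.5 s.e. bands); mean K over 500 replicates on a 33-tip tree
(3 s.e.); PGLS type-I error over 2 000 null replicates (expected in
[0.03, 0.07] at α = 0.05); slope recovery over 200 replicates (±5%);
permutation-p uniformity over 250 replicates of 99 permutations on a
12-tip tree (KS at the 1% level with a discreteness allowance).  The full
synthetic pipeline (33 species, 66 specimens, 999 permutations) runs in a
few seconds and reruns bit-identically.

## Known limitations

* NT resolution is limited by the winding estimator (~2e-3 turns with
  undulation); values genuinely at a sector boundary are credited to the
  higher sector by the snap rule.
* CW is not numerically identical to a manual single-slice measurement.
* The ABR correction is exact only when the offset profile is shared by
  the reference species; frequency-dependent deviations leave a residual
  bounded by the factor-grid interpolation error.
* Ancestral-state variances ignore uncertainty in the estimated BM rate.
* The Table-style grids treat shape PCs as predictors of one response at
  a time; a permutation-based multivariate-response reading is possible
  but not implemented.
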