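# Methods

This note documents the models behind pelletmetrics, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions the implementation commits to.

## Brightfield morphology pipeline

**Binarization.** Pellets appear dark on a bright background.  A pixel is
foreground when its intensity is below `(1 − sensitivity)` times the mean
intensity of its surrounding window (default window 65 px, sensitivity 0.1,
reflective padding).  Local-mean thresholding is robust to the slow
illumination gradients of inverse microscopes; the window must be larger
than typical pellets so the local mean is background-dominated.  Bright-mode
polarity binarizes the intensity-inverted image (min + max − I) with the
same rule, which makes the two polarities exactly symmetric.

**Hole filling.** Interiors of pellets larger than the window can binarize
bright (their local mean is itself dark), leaving ring-shaped masks; holes
are filled before segmentation, and the filled pixel count is logged.

**Watershed.** Touching pellets are split on the negated Euclidean distance
transform.  Markers are h-maxima of the distance transform (depth
`h_min = 2 px`); the transform is Gaussian-smoothed (σ = 1 px) before marker
detection because a rough mask boundary otherwise litters the ridge of an
elongated pellet with shallow spurious maxima that cut single objects in
two.  Any connected component left without a marker keeps one at its
distance peak, so foreground pixel count is conserved exactly.

**Measurement.** Area is the pixel count times the pixel area — no
sub-pixel refinement.  Perimeter uses the weighted boundary-step estimator
(diagonal steps weigh √2) as implemented in scikit-image; it reduces the
digitization bias of naive boundary counting but still measures digitized
circles a few percent away from 2πr, which is why measured circularities of
rendered circles sit near 0.95 rather than 1.0.  Circularity is reported
unclipped.  Feret extremes come from exact rotating calipers over the convex
hull of the region's pixel-corner points: the maximum is the hull diameter,
the minimum the smallest support width over hull edges (the minimum width of
a convex polygon is always attained flush with an edge).  A single-pixel
region has estimator perimeter 0 and gets circularity NaN.

**Filtering.** Objects with projected area below 200 μm² are debris;
objects with any pixel in the first/last row or column touch the edge.
Both are removed by default and counts are logged.  The filter is
idempotent and relabels survivors contiguously.

**Size distributions.** q0 is the count-weighted, q3 the d³-weighted
histogram density of d_a, binned from 0 at 20 μm width by default, each
normalized to unit integral.  The 20 μm default resolves populations with
~50–400 μm pellets without starving bins.

## CLSM viability pipeline

Each channel is binarized with Otsu's method, closed with a disk-shaped
structuring element of 5 px diameter, and hole-filled.  Two deliberate
choices:

* **Cross-channel hole filling.**  An enclosed region stained by neither
  channel (air bubble, sectioning gap) is an artifact and is filled; a hole
  in the green mask that the red channel stains is a dead core, not an
  artifact, and is preserved.  Blind per-channel filling would reclassify
  every enclosed dead core as overlap.  The rule is applied identically to
  both channels, so swapping the channels swaps live and dead shares
  exactly.
* **Unstained-channel guard.**  Otsu always splits a histogram, including
  pure background noise; a slice in which one stain did not bind would then
  contribute a half-frame speckle mask.  A channel whose Otsu classes are
  separated by fewer than 6 robust noise standard deviations (1.4826·MAD of
  the lower class) is treated as empty.  The standalone `binarize_otsu`
  stays pure Otsu and raises only on constant images.

"Total area" in the live ratio is the union of stained areas and "living"
is the solely-green region, matching the three-region decomposition; the
option `live_includes_overlap` provides the alternative convention in which
overlap pixels (alive and dead material in one voxel column) count as
living.  One equatorial slice represents the pellet; no multi-slice
aggregation is attempted.

## Pulse-shape flow cytometry

Profiles are four channels sampled against position (μm).  Conventions:

* **Baseline** per channel: median of the first and last three samples,
  subtracted before all areas and thresholds.
* **Extent**: first/last sample position where FSC exceeds the trigger
  (200 mV default).  This quantizes the diameter downward by at most one
  sample spacing per side.
* **Crossings** (SSC half-maximum, FLR threshold): linear interpolation
  between samples; lengths above a threshold sum sub-intervals (union, not
  the contiguous span).
* **Saturation**: ≥ 3 consecutive samples at ≥ 99 % of the clipping level.
  A particle is a *pellet* iff its FSC core saturates and its signal length
  exceeds 80 μm; else *large* (> 80 μm) or *small*.
* **FSC areas** use the clipped trace as recorded; no de-saturation
  extrapolation is attempted.
* The PI viable layer implements 0.5·(signal length − length above
  threshold).  The printed form of this quantity in the literature subtracts
  a length from a dimensionless 1; the difference-of-lengths reading is the
  only dimensionally consistent one and keeps the viability factor in
  [0, 1].
* The default viable layer feeding the viability factor is the FDA-based
  one; `layer="pi"` switches.  The optional 500 μm size-exclusion filter
  mirrors the sampling-bore limit of large-particle instruments.

Known properties worth remembering: FSC saturation shrinks the FSC area and
therefore *inflates* the FDA viable layer, more strongly for large pellets —
comparisons across size classes should prefer the PI layer or unsaturated
gains.  The 0.3-of-maximum threshold applied to a smooth projected dead
core crosses at 0.954·r_core, so vl_PI carries an inherent bias of
+0.023·d_core; with the default 2.5 μm sampling this stays below one sample
spacing for dead cores up to ≈ 100 μm, which bounds the regime in which the
PI estimate is quantitatively valid.

## Kinetics and statistics

dP/dt is discretized with central differences on interior points and
one-sided differences at the ends (non-uniform grids supported); q_P is
undefined (NaN, flagged) where X = 0 rather than infinite.  The one-way
ANOVA computes F from unequal-n sums of squares and takes p from the F
survival function; groups with fewer than two observations are rejected,
and zero within-group variance raises a degeneracy error instead of
reporting an infinite F.  Per-day comparisons run one test per day and
apply no multiple-testing correction across days; the output metadata says
so.  The type-I error of the implementation is verified by simulation
against the 99 % binomial interval of α = 0.05 over 500 null replicates.

## Synthetic generators — what they emulate, what they don't

All generators are bit-deterministic given parameters and seed.

**Brightfield frames.** Pellet cores are ellipses with log-normal
area-equivalent diameter (defaults: median 160 μm, log-sd 0.35, matching
shake-flask pellet populations at 4.5 μm/px), eccentricity uniform up to
0.6, anti-aliased edges (8×8 sub-pixel coverage), placed by rejection
sampling with minimum center distance = sum of semi-major radii + 2 px and
fully inside the frame; 1000 consecutive rejections raise a placement
error.  The fuzzy hyphal corona is a multiplicative radial darkening
(strength 0.25 of the core contrast, decay length 0.3 of the core radius)
with 25 % speckle; ground truth refers to the core ellipse only — where a
pellet "ends" has no observable definition, so the corona is texture the
segmentation is expected to reject.  Gaussian sensor noise (sd 4 on a
~140-unit contrast) completes the frame.  Not emulated: optical PSF,
photorealistic hyphae, depth-of-field, bead/pellet mechanics (bright
circular beads are available behind a flag for robustness tests).

**CLSM pairs.** Concentric geometry: green covers the section disk minus
the solely-red dead core, red covers the core plus the overlap band; truth
shares are the analytic circle-area ratios.  Not emulated: stain diffusion
gradients, bleaching, non-concentric necrosis.

**Pulse profiles.** The particle is an equatorial disk of diameter d; SSC
and FSC follow the projected chord 2·√(R²−x²) (which puts the SSC
half-maximum at ±R·√3/2 and makes the FSC area above baseline
gain·(π/4)·d²).  The FSC trace is floored at `edge_floor_mv` (400 mV)
inside the particle — the acquisition trigger is set below any biomass
signal precisely so that the recorded signal length represents the full
diameter — and clipped at the saturation level (2000 mV).  FLG follows the
projected viable shell (outer chord minus the chord of the inner
unstained sphere), FLR the projected dead core; unstained runs emit FLG as
a fixed autofluorescence ratio times the recorded FSC.  Under this model
the FDA viable layer has the closed form
R·(1 − (1 − t/R)²)·(g_FLG/g_FSC) for shell thickness t, which the tests
verify to 2 % on fine-sampled, unsaturated profiles.  Population defaults
(diameters log-normal ln 150/0.25 truncated to 80–280 μm per the
instrument's large-particle hindrance, dead cores 0.3·d, 2.5 μm sampling)
keep every per-particle recovery error within its analytic bound for any
seed.  Not emulated: time-to-distance conversion, optics, spectral
overlap beyond the FLR/FLG-ratio QC hook.

**Cultivation series.** Logistic biomass X(t) (X_max 5 g L⁻¹, rate
2.2 d⁻¹ — growth levels off around day 2), product P(t) rising along a
shifted logistic from onset day 3.5 (between day 3 and 4) toward P_max,
glucose coupled to grown biomass through a yield coefficient and clipped at
zero.  Noise-free trajectories are monotone where the model says they must
be.

Passing the synthetic-recovery tests demonstrates that the *pipelines are
correct and calibrated on data whose truth is known*; it does not certify
accuracy on real micrographs, whose artifacts (debris, focus drift,
touching coronas, staining heterogeneity) exceed what the generators
render.

## Problem sizes

The test suite and the acceptance script use 20 frames × 30 pellets for
segmentation recovery, a 5 × 5 staining-geometry grid at 5 % noise for
CLSM, populations of 200 pulse profiles, 500 null replicates for ANOVA
calibration and a 10-day × 2-condition demo run — sizes at which every
recovery bound above is provable and the whole acceptance run completes in
well under a minute on one core.

## Open choices made

* Watershed runs on the binary mask's distance transform, not on intensity.
* Whether beads appeared in analyzed micrographs is unknowable from
  image statistics alone; bead rendering and bead rejection both default
  to off.
* The "q_P at onset" summary value is q_P at the first sampling day
  strictly after the production onset.
* Per-day ANOVA is implemented for ≥ 2 groups although the comparison
  design is two-condition.
* CLSM live ratios are excluded from the demo's ANOVA table: one slice per
  sample point has no replication, and testing it would manufacture
  significance.
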