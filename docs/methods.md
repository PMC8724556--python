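# Methods

This note documents the models, parameter choices and numerical conventions
behind `organoidml`, and what the simulator-based validation does and does
not establish.

## Imaging model and conventions

Images are brightfield z-stacks, one per (well, field, day, channel), with
an optional co-registered far-red fluorescence channel for the vital dye.
All analysis runs on the per-pixel maximum intensity projection.  Pixel
indices are 0-based (row, column), row-major; physical coordinates in μm
are `index × pixel_size_um`.  Intensities are converted to float64 on load
with no rescaling — every downstream feature is either normalized or
standardized, so absolute calibration is not required.  Acquisition
geometry (pixel size, z start/step, filename template) comes from a YAML
run config, which overrides TIFF tags because instrument exports are
inconsistent.

## Segmentation

The texture stage is a supervised linear pixel classifier (logistic
regression, so the score is a probability thresholdable at 0.5) on five
per-pixel features at the texture scale σ_t: Gaussian-smoothed intensity,
gradient magnitude, both Hessian eigenvalues, and the intensity standard
deviation in a (2σ_t+1)² window.  The feature bank deliberately reuses the
same Gaussian-derivative operators as the SER features.  Training pixels
come from user strokes (default brush 15 px); features are standardized
over annotated pixels.  Polarity is learned from the annotations — there is
no hard assumption that organoids are dark.

The ROI pipeline is fixed: score → Gaussian smoothing at the region scale
σ_r (this is what makes region borders smooth) → threshold 0.5 → fill all
enclosed holes (4-connected background) → split clusters by watershed on
the negated interior distance transform, seeded at distance maxima at least
`min_split_distance_px` apart → drop components touching the border within
`border_margin_px` → drop components outside the area gate.  The distance
map is lightly smoothed (σ = 2 px) before seeding so that ragged granular
boundaries do not spawn spurious seeds; any component left without a seed
receives one at its distance maximum, so no foreground is silently lost.
Components are 8-connected throughout.

Defaults: σ_t = 2 px, σ_r = 6 px, brush 15 px, minimum split distance
20 px, area gate 700–200,000 μm² (≈ 30–500 μm equivalent diameter — wide
enough for the assay's 30–300 μm organoids while excluding debris and
unsplit clusters), border margin 0 (touching the edge already disqualifies).

## The 25-feature panel

All intensity-derived features work on the contrast image
J = clip(background_median − I, 0) for dark objects (configurable to
bright), with the background median estimated from non-foreground pixels
per image.  This makes bright/dark/weight semantics polarity-consistent and
the whole panel invariant under I → cI.

**SER (8).** Gaussian derivatives of J at σ_ser = 2 px give the gradient
(Jx, Jy) and Hessian eigenvalues λ₁ ≥ λ₂ per pixel.  Operators:
edge = √(Jx²+Jy²); spot = √(max(−λ₁,0)·max(−λ₂,0));
hole = √(max(λ₁,0)·max(λ₂,0)); saddle = √(max(λ₁,0)·max(−λ₂,0));
ridge = max(−λ₂,0)·max(1−|λ₁|/|λ₂|,0) when λ₂ < 0, else 0;
valley = λ₁·max(1−|λ₂|/λ₁,0) when λ₁ > 0, else 0;
bright/dark = positive/negative deviation of J from its ROI mean.  Each
feature is the ROI mean of the squared operator divided by the squared
mean ROI intensity of the original image.

**STAR (17).** Area = pixel count × pixel size².  The mask's second-moment
ellipse gives Length/Width = 4√λ (px→μm) and Ratio Width to Length =
√(λmin/λmax); Roundness = 4πA/P².  Intensity-weighted (weights = J) second
moments give Axial Small Length and Axial Length Ratio.  Radial Mean /
Radial Relative Deviation are the mean and relative spread of pixel
distances to the weighted centroid.  Profile zones split the ROI at half of
the normalized interior depth (distance-to-border / max depth); Profile i/2
is the zone-mean of J over the ROI mean of J.  Symmetry k = 1 − |k-th
circular harmonic of the angular mass distribution of J about the weighted
centroid| / total mass, computed on 36 angular bins (10°), harmonics 2–5.
Threshold Compactness X% is 4πA/P² of the sub-region with J at or above the
X-th within-ROI percentile (linearly interpolated percentile, ≥ rule).

Degenerate inputs: ROIs under 9 px are rejected and counted; zero-contrast
ROIs fall back to uniform weights for the weighted moments and symmetry
(shape-only), profile ratios default to 1 with a flag; an empty profile
zone copies the other zone's value with a flag.

### Numerical conventions

- Gaussian-derivative kernels are sampled Gaussians truncated at 4σ.  The
  sampled second-derivative kernel does not sum exactly to zero, so it is
  DC-corrected (residual sum removed along the order-0 kernel); derivative
  responses to constant images are then exactly zero and derivative planes
  are exactly invariant under constant offsets.  Borders use symmetric
  (reflect) padding.
- Per-ROI filtering happens on the bounding box expanded by the kernel
  radius, which yields bit-identical values to filtering the whole image at
  every ROI pixel while keeping cost proportional to ROI size.
- The perimeter estimate is the weighted boundary-pixel count of
  Benkrid–Crookes (Vossepoel–Smeulders-style corrections, via
  scikit-image); a rasterized disk has compactness ≈ 0.91, and compactness
  values can slightly exceed 1 for smooth large regions (the documented
  (0, ~1.1] range).
- Every fast implementation is validated against a naive reference
  (explicit 2D kernel sums per pixel, per-pixel moment loops, a
  from-definition perimeter) to 10⁻⁶ relative on 64×64 fixtures; measured
  agreement is at machine precision.

## Live/dead classifier

`ViabilityClassifier` is a scikit-learn-style estimator.  Features are
z-standardized from the training data.  Greedy forward selection maximizes
stratified cross-validated accuracy (5 folds × 5 repeated shuffles,
derandomized from the seed); a feature is added only if it improves the
running best CV accuracy by at least 0.5 percentage points, with ties
resolved toward the smaller model and panel order.  Fresh fold splits are
drawn at every greedy step so the winner's-curse inflation of one step's
best score does not leak into the next comparison — on label-shuffled data
the search stops at zero or one feature instead of chasing noise.  If no
feature clears the bar, the model degenerates to a constant majority-class
call.  The final model is a ridge-regularized linear discriminant
(`lsqr`, shrinkage chosen by the same CV from {0, 10⁻³, 10⁻², 10⁻¹}).

Goodness is the signed margin (w·x_std + b) divided by the pooled
within-class standard deviation of the training projection — a
signal-to-noise distance from the decision boundary.  Goodness > 0 ⇒ live;
exactly 0 ⇒ dead, the conservative choice for viability claims.  The model
serializes to JSON (features, weights, bias, standardization, goodness
scale, seed, selection report) and round-trips with bitwise-equal
predictions.

## Vital-dye calling

A DRAQ7 threshold is either absolute or background median + 5×MAD of the
fluorescence outside all ROIs (robust to the rare bright spots).  An ROI is
dead iff it contains at least `min_count` (default 1) 8-connected
above-threshold components of area ≥ `min_positive_area_um2`.  The nucleus
reference area is a config parameter (default 65 μm², a ~9 μm nucleus);
the boundary is inclusive.  Calls are monotone: adding positive area can
only move live → dead, and raising the floor can only reduce dead calls.

## Quantification

Tracking links consecutive imaging days by an exact optimal assignment on
centroid distances with a hard gate (default 50 μm per step; day gaps count
as one step).  The objective is made precise as: minimize the sum of
matched distances plus one gate penalty per unmatched organoid on either
side — equivalently, a pair is worth matching exactly when its distance is
within the gate.  It is solved on an augmented square cost matrix with the
Hungarian algorithm and verified against exhaustive enumeration on small
instances.  Merges/splits are treated as track loss plus a new track.

Response curves: per well and day, live proportion (live/total) or ratio
(live/dead); replicate wells of a condition give mean and sample standard
deviation; optional normalization divides a condition's curve by its own
day-0 mean (a zero reference flags the curve as missing rather than
crashing).

Fleiss' κ uses the standard estimator on a balanced subjects × categories
count table; z = κ/SE with the classic large-sample null standard error and
a two-sided normal p-value.  κ is cross-checked against statsmodels;
percent agreement and strict-majority consensus (exact tie →
indeterminate, excluded downstream) cover the two-method comparisons.

Heatmap matrices average per-well class means across wells per
(treatment, day) group, z-score each feature row across groups (sample sd;
constant rows become zeros and are flagged), and order rows and columns by
agglomerative clustering (Euclidean, complete linkage) with name-sorted
inputs so ties break deterministically.

## The simulator

The synthetic plate generator defines the study conditions all validation
runs under.  A 512×512 field at 2 μm/px (~1 mm) holds 30–38 non-touching
organoids per well (rejection-sampled, largest first, with a 10 μm minimum
edge-to-edge gap and a margin reserving growth, post-mortem spread and
boundary perturbation; an optional border fraction deliberately overlaps
the field edge to exercise the border filter).  Radii are lognormal
(median 28 μm initial, clipped 22–70 μm), growing 1.5 μm/day while alive.

Live organoids render as smooth dark disks (base attenuation 0.35 of a
300-intensity contrast on a 1000-intensity background), with a darker rim
and a brighter lumen; dead organoids have harmonically perturbed
boundaries (harmonics 3–7, bounded to ±25% of the radius), granular
interiors (smoothed white noise, σ 0.8 px) and a 1.12× spread.  Each
organoid carries multiplicative phenotype jitter (texture gain, granule
gain, rim gain, lumen depth, overall attenuation) wide enough that no
single feature separates the classes perfectly — the heterogeneity that
forces the classifier to combine texture and morphology, as real organoid
panels do.

Death is an exponential waiting time with hazard/day = baseline +
h_max·doseᵞ/(doseᵞ + EC50ᵞ) (defaults h_max 0.4/day, EC50 10 μM, γ = 1,
baseline 0); positive-control wells saturate at baseline + h_max.  Dead
organoids receive 1 + Poisson(3) nucleus-scale dye spots (lognormal areas,
median 110 μm² — comfortably above the 65 μm² call floor even after
2 μm/px rasterization); each spot is retained at each subsequent imaging
day with probability 1 − dye_loss_prob (default 0.3; the divergence
benchmark uses 0.5).  This produces the characteristic failure mode where
dye-based dead counts fall behind the label-free classifier over time.

Written z-stacks put the rendered scene in plane 0 and scene-minus-random-
dimming in deeper planes, so the maximum projection reconstructs the scene
exactly while the projection step is still exercised end to end.  All
randomness derives from per-well / per-organoid / per-day substreams of the
config seed, so outputs are bitwise reproducible and independent of
iteration order.

### What the simulator does and does not show

Passing the benchmarks shows the pipeline is internally correct: the
implemented operators match their definitions, segmentation recovers known
objects, the classifier learns the rendered live/dead contrast, and the
aggregation arithmetic is exact.  It does not show performance on real
brightfield data — the simulator has no optics (no PSF, no defocus
blending across z), a flat background with Gaussian noise, no touching or
overlapping organoids beyond the border cases, no debris, and idealized
dye photophysics.  Real deployments must retrain the texture model and
classifier on their own annotations; the defaults here are study
conditions, not universal constants.

## Benchmark problem sizes

The acceptance benchmarks run at desk scale by design: 3 random 64×64
fixtures for operator agreement; 20 seeded scenes (~670 organoids) for
segmentation; 1000 patches (500/500) for classifier accuracy; a 9-well,
4-day plate (~1200 ROIs) for the end-to-end curve comparison and the
vital-dye divergence; 500 simulated subjects for the chance-level κ check.

## Known limitations

- The SER/STAR operator definitions are a documented reimplementation of a
  proprietary feature family from its published descriptions; values are
  validated against this package's own definitions, not vendor output.
- Interactive segmentation touch-ups (manual split/merge) are out of
  scope; parameters are exposed instead.
- Tracking has no appearance model; large displacements or organoid
  merging read as track loss plus birth.
- Curves are reported, not fitted — no EC50 estimation.
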