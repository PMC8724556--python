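# organoidml

Label-free, image-based analysis of patient-derived tumor organoid (PDO)
drug response from brightfield microscopy.

## The problem

Patient-derived organoids are a 3D preclinical model for oncology drug
testing, but reading out their viability is awkward: ATP assays destroy the
sample and pool everything in a well, and vital dyes such as DRAQ7 are both
transient (dying cells eventually stop retaining the dye) and confounded by
necrotic cores in large healthy organoids.  This package implements a
label-free alternative: organoids are imaged in brightfield z-stacks over a
treatment time course (days 0, 1, 3, 7), each z-stack is collapsed to its
maximum intensity projection, individual organoids are segmented as regions
of interest (ROIs), each ROI is described by a 25-feature texture +
morphology panel, and a linear classifier calls each organoid *live* or
*dead* with a signal-to-noise score ("goodness").  Because imaging is
non-destructive, individual organoids can be tracked across days and
well-level live-fraction response curves computed per treatment and dose.

## The method

- **Segmentation** — a supervised per-pixel texture classifier (linear, on
  Gaussian-derivative features at a 2 px texture scale) separates organoid
  from background; the class score is smoothed at a 6 px region scale,
  thresholded at 0.5, hole-filled, and touching organoids are split by a
  seeded watershed on the interior distance transform.  Border-touching
  components and components outside the 700–200,000 μm² area gate are
  discarded.
- **Features** — 8 SER (Spot/Hole/Edge/Ridge/Valley/Saddle/Bright/Dark)
  texture features from the gradient and Hessian eigenvalues (λ₁ ≥ λ₂) of
  the contrast image *J* = clip(background − *I*, 0) at σ = 2 px, each the
  ROI mean of the squared operator normalized by the squared mean ROI
  intensity; and 17 STAR morphology features (Area, Roundness, axis lengths
  and ratios from mask and intensity-weighted second moments, radial
  statistics, two interior-depth profile zones, circular-harmonic
  symmetries 2–5, and threshold compactness at the 50th/60th within-ROI
  contrast percentiles).
- **Classifier** — features are z-standardized; greedy forward selection by
  stratified cross-validated accuracy picks the discriminative subset; a
  ridge-regularized linear discriminant is fit on the survivors.  The
  goodness of a sample is its signed margin w·x + b in pooled within-class
  standard-deviation units; goodness > 0 ⇒ live, exact 0 ⇒ dead.
- **Vital dye** — an organoid is DRAQ7-dead when its ROI contains at least
  one 8-connected dye-positive area at least the size of a nucleus
  (default 65 μm²).
- **Quantification** — per-organoid tracking by optimal centroid assignment
  with a displacement gate; per-well live/dead counts and class-wise
  feature means; replicate-averaged response curves (proportion live/total
  or live/dead ratio, optionally normalized to day 0); percent agreement,
  majority vote and Fleiss' κ (with its large-sample z test) for
  method/rater concordance; row-z-scored, hierarchically clustered
  feature × (treatment, day) heatmap matrices.
- **Simulator** — a synthetic plate generator with per-organoid ground
  truth: smooth lumen-bearing live organoids vs granular, irregular dead
  ones; dose- and time-dependent death via an exponential waiting time with
  Hill-of-dose hazard; a fluorescence channel with nucleus-sized spots in
  dead organoids that can be lost at later timepoints, reproducing the
  transient-dye failure mode.

## Worked example

Simulate a two-condition plate (media control vs 5 μM staurosporine kill
control, 3 replicate wells), train the texture model and classifier, and
compute normalized response curves:

```python
from organoidml import VDParams, train_classifier
from organoidml.simulate import (SimConfig, make_wells, simulate_plate,
                                 make_training_fixture, patch_features)
from organoidml.pipeline import texture_model_from_plate, analyze_plate
from organoidml.quantify import summarize_wells, response_curves

wells = make_wells([("media", 0.0, "negative"),
                    ("staurosporine", 5.0, "positive")], n_replicates=3)
plate = simulate_plate(SimConfig(wells=wells, seed=7))
texture = texture_model_from_plate(plate, seed=0)
patches = make_training_fixture(plate.config, n_live=80, n_dead=99, seed=11)
examples = patch_features(patches, texture_model=texture)
model, report = train_classifier(examples, seed=17)
print("selected features:", model.selected_features_)

analysis = analyze_plate(plate, texture, model, vd_params=VDParams())
summaries = summarize_wells(analysis.calls[["well", "day", "roi_id", "label"]],
                            analysis.features, plate.layout)
curves = response_curves(summaries, plate.layout, mode="proportion", normalize=True)
print(curves.to_string(index=False))
```

Output:

```
selected features: ['Profile 1/2', 'SER Bright']
      condition  day       mode     mean       sd  n_wells  normalized
        media_0    0 proportion 1.000000 0.033419        3        True
        media_0    1 proportion 1.031475 0.000000        3        True
        media_0    3 proportion 1.020384 0.019210        3        True
        media_0    7 proportion 1.031475 0.000000        3        True
staurosporine_5    0 proportion 1.000000 0.000000        3        True
staurosporine_5    1 proportion 0.681962 0.054870        3        True
staurosporine_5    3 proportion 0.280423 0.055744        3        True
staurosporine_5    7 proportion 0.087759 0.052060        3        True
```

The training set is 179 labeled organoids (80 live from media controls, 99
dead from the staurosporine control); selection picked one morphology
feature (the outer interior-depth profile zone) and one texture feature.
Untreated wells stay at a normalized live proportion of ~1 across the week
while the kill control collapses from 1.0 to 0.09 by day 7, with
replicate-well standard deviations of ~0.05.

A command-line interface mirrors the workflow for on-disk data
(`organoidml simulate / segment / features / train / classify / vitaldye /
track / summarize / concordance / heatmap`).

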