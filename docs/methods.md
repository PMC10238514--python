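# Methods

`catpain` re-implements, as a reusable pipeline, a landmark-based approach to
automated pain recognition in cats: 48 manually annotated facial landmarks
per image, Glasgow composite measure pain scale (CMPS-feline) metadata
driving the pain / no-pain class assignment, classifiers evaluated under
subject-disjoint cross-validation, and a three-instrument explainability
battery asking *which facial regions the models rely on*.  Because the
clinical dataset this design comes from is available only on request, the
package ships a synthetic cohort generator with planted region effects, so
every downstream claim can be checked against known ground truth.

## Data model

One observation is a `LandmarkSet`: 48 (x, y) pixel coordinates (x right,
y down, origin top-left) plus image and subject identifiers.  A `RegionMap`
partitions indices into **ears**, **eyes** and **mouth** (nose/mouth area);
the published 48-point scheme does not enumerate per-region counts, so the
default split (ears 10, eyes 14, mouth 24) is a declared stand-in, shipped
as data and overridable from a JSON file.  Cohort metadata rows carry sex,
neuter status, breed, age (possibly unknown), free-text clinical condition,
an integer CMPS score in [0, 20] and a suspected-pain flag.

## Class assignment

With the CMPS intervention threshold at 5:

* `pain`     — CMPS ≥ 5 **and** clinical suspicion of pain;
* `no_pain`  — CMPS < 4 **and** no clinical suspicion;
* excluded   — CMPS = 4 (read over integers, so the excluded band is exactly
  {4}); CMPS ≥ 5 without suspicion; CMPS ≤ 3 with suspicion; and records
  flagged for clinical exclusion (brachycephaly, facial wounds, neurological
  disease — consumed as a boolean, never computed).

Every exclusion is logged with its triggering rule.  Duplicate subject ids
are rejected outright: the design admits one frame per individual.  Class
balancing is uniform random undersampling of the majority class, seeded.
Applied to the bundled 84-cat reference table the rules yield 42 / 42, which
the acceptance suite asserts.

## Alignment

A two-point similarity fit: the unique scale/rotation/translation mapping
the set's two eye centers (the mean of each eye region's landmarks) onto the
template's canonical eye-center targets.  The two-point fit is exact, which
realizes the property the image branch depends on — after alignment all eye
centers occupy the same pixel positions, so one *shared* horizontal band
decomposition (ears band above the eye band, mouth band below; integer rows,
half-open at the top, boundary rows belonging to the lower band) is valid
for every image.  Degenerate inputs (coincident eye centers) raise rather
than produce an unstable fit.

## Features

* **Flat coordinates** — the fixed order x0,y0,…,x47,y47 (96 features), the
  perceptron's input representation and the one on which per-landmark Gini
  importance is defined (a landmark's importance is the sum over its x and y
  features).
* **Multi-region vectors** — ordered within-region landmark pairs; default
  scheme is the consecutive-pairs chain inside each region, displacement
  encoding (x_j − x_i, y_j − y_i), which is translation invariant.  Both the
  adjacency list and the encoding are configurable; occlusion and importance
  aggregation depend only on per-feature *tags* (region + contributing
  landmarks), insulating results from this choice.
* **Augmentation** — `rep` jittered copies per original, i.i.d. uniform
  noise on [−M·d, +M·d] per coordinate with d the set's inter-ocular
  distance, so the magnitude M is scale-free across cats.  Copies inherit
  their source's subject id and label; augmentation is applied to training
  folds only (standard leakage hygiene — whether the original protocol also
  augmented test folds is not stated anywhere, so the conservative choice is
  made and recorded here).

## Models and validation

Ten-fold cross-validation with **no subject overlap**: folds are dealt over
shuffled subjects, all of a subject's samples (including augmented copies)
follow it, and a train/test subject intersection aborts the run.  Metrics
are accuracy, precision and recall (positive class = pain), averaged
unweighted over folds; a fold with no positive prediction reports precision
as a flagged null, not zero.  The pooled-prediction (micro) alternative was
considered and rejected to keep per-fold variability visible.

* **Random forest** — scikit-learn; the full hyperparameter grid spans
  MaxDepth 1–40 and Trees 1–246 in steps of 5, selected by *nested* inner
  subject-disjoint CV on the training folds (selection on outer test folds
  would be optimistically biased; the original protocol does not say which
  was used).  Ties break toward smaller depth, then fewer trees.
  `class_weight="balanced"` compensates the incidental train-fold imbalance
  that subject-wise folds induce on a balanced-by-design cohort; without it
  the no-signal control sits visibly below 0.5 because trees inherit the
  train fold's majority prior.  Explainability runs fix the forest at
  MaxDepth 20 / Trees 221 (the operating point of the occlusion protocol)
  so that all occlusion rows differ only in their inputs; analysis scripts
  demonstrate the grid search on a reduced grid (depths {1,5,10,20} ×
  trees {61,121,221}) as this package's desk-scale problem size.
* **MLP** — 96-unit input, one rectified hidden layer of 64 units, input
  standardization, early stopping.  The original architecture beyond the
  input layer is not restated in the source design, so this is a declared,
  configurable stand-in.
* **Convolutional stand-in** — the image branch's classifier: a small numpy
  network (single conv layer, 8 filters 5×5 stride 2, ReLU, global average
  pooling, linear head) trained full-batch with Adam on 64×64 downsampled
  renders.  It replaces transfer-learned deep networks, which are outside
  this package's scope; the occlusion and saliency machinery treats it
  identically to any convolutional model.

## Explainability instruments

* **Occlusion** — seven configurations (full; reveal-only and hide for each
  region), one shared fold plan and seed across configurations.  Landmark
  models drop/keep tagged feature vectors; the image model masks band rows
  with black (fill value 0; configurable — the convention is not dictated by
  anything upstream).  A configuration with zero surviving features becomes
  a failed row with NaN metrics, never a silent skip.
* **MDI importance** — per-landmark sum of the fitted forest's
  mean-decrease-in-impurity feature importances, min-max normalized to
  [0, 1], highlighted at ≥ 0.5.  Region aggregates are means of raw
  importance, also reported as ears-normalized ratios.
* **Grad-CAM heat** — for the GAP-headed stand-in the channel weights are
  the head weights of the target class (the gradient of the class score with
  respect to the pooled activations), the map is rectified, upsampled and
  scaled to [0, 1].  Heat(L, I) is the heatmap value at landmark L's pixel
  (nearest-integer rounding, clamped at raster edges; landmarks beyond the
  raster raise).  Per-landmark averages are normalized so the hottest
  landmark reads 255; region means and ears = 1.00 ratios follow.  When
  ingesting RGB-rendered heatmaps the red channel is the scalar heat
  (configurable); internally heat is the raw saliency scalar.
* **Consistency summary** — per approach/instrument, the highest- and
  lowest-ranked region; the agreement flag holds when every reveal-only,
  importance and heat row names the same highest and same lowest region
  (hide rows are displayed but excluded — their expected pattern is the
  inverse).

## The synthetic cohort generator

Defaults are the study conditions: 42 subjects per class on a 256×256
canvas; planted effect in the mouth region with peak amplitude 12 px;
subject-level similarity perturbation of scale 3 px (translation in px;
rotation and log-scale scaled by the inter-ocular distance); annotation
jitter 1.5 px per coordinate; CMPS drawn uniformly in [5, 11] for pain and
[0, 3] for no-pain subjects (scores of 4 are never generated, but the
filters still handle them); suspected-pain flag true exactly for the pain
class.  Everything is reproducible from one integer seed.

The pain displacement field needed care.  A naive globally smooth radial
field moves the eye centers, and eye-center alignment then converts that
motion into a whole-face similarity correction — which makes the *ears*
strongly class-informative even though the field barely touches them (we
measured reveal-only-ears CV accuracy of 0.93 under such a field).  The
final field therefore has two components, both alignment-neutral:

1. a smooth radial push away from the mouth-region centroid, Gaussian
   falloff (scale 1.2 × the region's RMS radius), applied to mouth landmarks
   only — mean displacement ≈ 8.5 px at the default amplitude;
2. an orbital-tightening component: each eye compressed toward its own
   center by 0.08 of the effect size (≈ 1 px at default).  Compression about
   an eye's center leaves that center — the alignment anchor — fixed, so the
   secondary effect is pure shape.  Grimace scales pair muzzle tension with
   orbital tightening, which is the pattern this emulates.

Ears move by exactly zero, making them the null region.  The amplitudes
were chosen so the three regions are cleanly ordered for the recovery
checks: mouth-only models reach ≈ 1.0 CV accuracy, eyes-only ≈ 0.75–0.8,
ears-only ≈ 0.5.

Renders are schematic: a fixed head disk plus filled region polygons
anchored at the landmarks, so pixel content moves with — and only with —
each region's landmarks.  Synthetic heatmaps are Gaussian bumps on a chosen
region, for exercising the heat aggregation independently of any model.

**What the generator does not emulate:** photographic appearance, fur and
lighting, breed-specific craniofacial morphology, correlated (non-i.i.d.)
annotator error, and any coupling between metadata (age, sex, breed) and
face shape.  Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and its instruments agree on planted
structure — not that real clinical accuracies are reproduced.  The original
study's headline numbers (accuracies near 0.78 for the landmark branch, and
its region ratios) depend on the private dataset and are deliberately not
acceptance targets here.

## Numerical and protocol choices

* Band rows are integers, half-open at the top; tie rows belong to the
  lower band — masks are bit-exact and the three bands tile the height.
* Landmark→pixel reads round to nearest and clamp at edges; landmarks more
  than half a pixel outside the raster raise with image and landmark named.
* Min-max normalization of a constant importance vector defines all
  landmarks as maximal (normalized 1) rather than dividing by zero.
* A fold with no positive predictions reports precision as a flagged null
  (excluded from the fold average); a fold with no positive *samples*
  reports recall as 0, conservatively.  Region ratios against a
  zero-importance ears region are undefined; shares of total importance are
  reported where a denominator could vanish.
* ICC(2,1) (two-way random effects, absolute agreement, single rater) is
  computed from the classical ANOVA mean squares, vectorized over the 96
  coordinate measurands; the pooled summary is the mean over coordinates.
  Coordinates with zero variance across images yield NaN and are excluded
  from the pooled mean.  No acceptability threshold is imposed — the
  statistic is reported and thresholds are left to configuration.
* Seeds: every stochastic stage (cohort draw, fold dealing, model fits,
  augmentation) consumes an explicit seed derived from the run seed via
  `numpy.random.SeedSequence`.

## Problem sizes

The test and acceptance runs use 84-subject cohorts (the reference design
scale), ten seed replicates for the planted-signal battery, ten folds, and
the fixed-operating-point forest; the full 40 × 50 hyperparameter grid is
exercised only at reduced size.  These are this package's chosen desk-scale
problem sizes; all of them are single knobs if larger runs are wanted.

## Known limitations

* The landmark template is synthetic; its coordinates are not the published
  scheme's and conclusions about specific landmark indices do not transfer.
* The convolutional stand-in is far smaller than production image models;
  its Grad-CAM maps are coarse (14×14 before upsampling).
* The MLP stand-in's architecture beyond the input layer is a default, not
  a reconstruction.
* Statistical testing of region differences is out of scope (none is
  defined for these instruments here); the consistency summary is ordinal.
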