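# catpain

Automated pain recognition in cats from facial landmarks, with a full
explainability battery — built as a reusable pipeline and exercised end to
end on a synthetic cohort generator with planted, known facial effects.

## The problem

Cats are notoriously hard to assess for pain.  Behaviour-based instruments
such as the Glasgow composite measure pain scale (CMPS-feline, 0–20 points,
intervention threshold ≥ 5) and facial grimace scales exist, but they rely
on trained human scorers.  A machine alternative works from face images: 48
anatomical landmarks annotated per image, a cohort metadata table carrying
each cat's CMPS score and a suspected-pain flag, and classifiers trained to
separate *pain* from *no pain* under cross-validation with no subject
overlap.  Beyond accuracy, the scientific question is *which facial regions
(ears, eyes, nose/mouth) the models rely on* — answered here with three
independent instruments:

1. **Occlusion studies** — retrain with one region's information removed
   (*hide*) or exclusively retained (*reveal only*) and compare accuracies;
2. **Gini importance** — per-landmark Mean Decrease in Impurity of a random
   forest, each landmark scoring the sum of its x- and y-feature
   importances, min-max normalized;
3. **Grad-CAM heat** — saliency of a convolutional image classifier read
   out at each landmark's pixel: `Heat(L, I)` is the heatmap value at L's
   coordinates on image I, averaged over images, scaled so the hottest
   landmark reads 255, and aggregated per region as ears-normalized ratios.

The clinical dataset that motivated this design is available only on
request, so the package ships (a) the published 84-cat cohort *metadata*
table, on which the CMPS class rules must reproduce the 42 / 42 split, and
(b) a synthetic landmark/image generator whose planted region effect gives
every instrument a ground truth to recover.

## What's in the box

```
src/catpain/       the library
  template.py        canonical symmetric 48-landmark face template
  synthetic.py       cohort generator: planted effects, renders, heatmaps
  cohort.py          metadata IO, CMPS class rules, balancing, ICC(2,1)
  geometry.py        eye-center similarity alignment, region bands, masking
  features.py        flat coordinates, multi-region vectors, augmentation
  classify.py        RF / MLP / CNN under subject-disjoint 10-fold CV
  cnn.py             numpy convolutional stand-in with Grad-CAM
  explain.py         occlusion studies, MDI importance, heat aggregation
  pipeline.py        end-to-end study drivers
  cli.py             `catpain simulate|run|explain|report`
analysis/          numbered narrative drivers writing results/ tables
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py (see below)
```

## Worked example

```python
import numpy as np
from catpain import ModelSpec, occlusion_study
from catpain.pipeline import EXPLAIN_RF, generate_study

bundle = generate_study(seed=42)       # 42+42 cats, aligned, rendered
study = occlusion_study(
    bundle.dataset(aligned=True),
    ModelSpec("random_forest", seed=42, **EXPLAIN_RF),
    bundle.fold_plan,
)
print(study.table)
```

prints the seven-configuration occlusion table for the planted-muzzle
cohort (10-fold subject-disjoint CV accuracies):

```
  Region       Config  Accuracy  Precision    Recall
0    All         Full  1.000000   1.000000  1.000000
1   Ears  Reveal only  0.491667   0.509788  0.630000
2   Ears         Hide  1.000000   1.000000  1.000000
3   Eyes  Reveal only  0.855556   0.865000  0.868333
4   Eyes         Hide  1.000000   1.000000  1.000000
5  Mouth  Reveal only  1.000000   1.000000  1.000000
6  Mouth         Hide  0.806944   0.865000  0.786667
```

Read it as the instruments would: the mouth region alone suffices (reveal
only = 1.0) and hiding it hurts; the ears alone are at chance (0.492) and
hiding them costs nothing — exactly the planted structure, with the eyes'
secondary orbital-tightening effect in between.  The same bundle feeds the
forest's per-landmark MDI map and the CNN's Grad-CAM heat profile, and
`catpain.explain.consistency_summary` checks that all three instruments
name the same highest and lowest region.

The numbered scripts under `analysis/` run the complete study — cohort
simulation, CMPS filtering on the bundled clinical table, the
model-comparison table (alignment × augmentation × RF/MLP/CNN), occlusion
studies per model, importance and heat profiles, and multi-seed consistency
— each printing what it found and writing CSVs under `results/analysis/`.

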