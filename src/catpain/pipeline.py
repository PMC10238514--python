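"""End-to-end study pipelines over the synthetic cohorts.

These functions wire the stages together exactly as the analysis scripts,
the CLI and the acceptance checks consume them:

* :func:`generate_study` — simulate a cohort, apply the CMPS class filters,
  align to the template, render faces, compute shared region bands;
* :func:`planted_signal_run` — the full explainability battery (occlusion,
  MDI importance, Grad-CAM heat, consistency summary) on one seed;
* :func:`null_calibration_run` — the no-signal control (effect size 0).

The default :class:`~catpain.synthetic.CohortParams` are the study
conditions; per-seed replicates vary only the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .classify import (
    CVResult, Dataset, FoldPlan, GridSpec, ModelSpec, build_estimator,
    cross_validate, make_subject_folds,
)
from .cohort import PAIN, LabeledCohort, assign_classes, records_from_frame
from .explain import (
    ConsistencySummary, HeatProfile, ImportanceMap, OcclusionStudy,
    consistency_summary, gradcam, heat_at_landmarks, landmark_importance_mdi,
    occlusion_study,
)
from .features import AugmentParams, featurize_sets
from .geometry import RegionBands, align_landmarks, compute_region_bands
from .landmarks import LandmarkSet
from .synthetic import CohortParams, render_face, simulate_cohort
from .template import LandmarkTemplate, make_template

#: Explainability runs fix the forest at the protocol's chosen operating
#: point (MaxDepth 20, Trees 221) so occlusion rows are comparable and fast.
EXPLAIN_RF = dict(max_depth=20, n_trees=221)

K_FOLDS = 10


def _subseeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class StudyBundle:
    """One simulated cohort, filtered, aligned, rendered, band-decomposed."""

    params: CohortParams
    template: LandmarkTemplate
    cohort: pd.DataFrame
    labeled: LabeledCohort
    sets: list[LandmarkSet]
    aligned: list[LandmarkSet]
    labels: np.ndarray          # per set, 1 = pain
    subjects: np.ndarray
    renders: np.ndarray | None = None
    bands: RegionBands | None = None
    fold_plan: FoldPlan | None = None

    def dataset(self, aligned: bool = True, featurizer=None, with_images: bool = False) -> Dataset:
        return Dataset(
            labels=self.labels,
            subject_ids=self.subjects,
            sets=self.aligned if aligned else self.sets,
            images=self.renders if with_images else None,
            featurizer=featurizer,
            template=self.template,
            approach="DL" if with_images else "LDM",
            align_flag="Yes" if aligned else "No",
        )


def generate_study(
    seed: int,
    params: CohortParams | None = None,
    canvas_size: tuple[int, int] = (256, 256),
    render: bool = True,
    k_folds: int = K_FOLDS,
) -> StudyBundle:
    """Simulate, filter, align and (optionally) render one cohort."""
    seed_cohort, seed_folds = _subseeds(seed, 2)
    if params is None:
        params = CohortParams(seed=seed_cohort)
    template = make_template(canvas_size)
    cohort, sets = simulate_cohort(template, params)
    labeled = assign_classes(records_from_frame(cohort))
    label_of = {r.subject_id: int(l == PAIN) for r, l in zip(labeled.records, labeled.labels)}
    sets = [s for s in sets if s.subject_id in label_of]
    aligned = [align_landmarks(s, template)[0] for s in sets]
    labels = np.array([label_of[s.subject_id] for s in sets])
    subjects = np.array([s.subject_id for s in sets])

    renders = bands = None
    if render:
        bands = compute_region_bands(aligned, canvas_size[1], template)
        renders = np.stack(
            [render_face(s, canvas_size, template.region_map) for s in aligned]
        ).astype(float) / 255.0
    fold_plan = make_subject_folds(subjects, k_folds, seed_folds)
    return StudyBundle(params, template, cohort, labeled, sets, aligned,
                       labels, subjects, renders, bands, fold_plan)


def fit_importance_forest(bundle: StudyBundle, seed: int) -> tuple[ImportanceMap, object]:
    """RF on the flat 96 coordinates of the aligned cohort, MDI per landmark."""
    X, tags = featurize_sets(bundle.aligned, None, bundle.template.region_map)
    spec = ModelSpec("random_forest", seed=seed, **EXPLAIN_RF)
    forest = build_estimator(spec)
    forest.fit(X, bundle.labels)
    return landmark_importance_mdi(forest, tags, bundle.template.region_map), forest


def gradcam_heat_profile(bundle: StudyBundle, seed: int) -> tuple[HeatProfile, "object", list]:
    """Train the CNN stand-in on the renders, Grad-CAM every image at its
    predicted class, and aggregate heat at the aligned landmarks."""
    spec = ModelSpec("cnn_standin", seed=seed)
    model = build_estimator(spec)
    model.fit(bundle.renders, bundle.labels)
    predicted = model.predict(bundle.renders)
    h = bundle.template.canvas_size[1]
    w = bundle.template.canvas_size[0]
    heatmaps = [
        resize(gradcam(model, im, int(cls)), (h, w), order=1, preserve_range=True)
        for im, cls in zip(bundle.renders, predicted)
    ]
    profile = heat_at_landmarks(heatmaps, bundle.aligned, bundle.template.region_map)
    return profile, model, heatmaps


@dataclass
class PlantedRun:
    """All explainability outputs of one planted-signal replicate."""

    bundle: StudyBundle
    occlusion: OcclusionStudy
    importance: ImportanceMap
    heat: HeatProfile
    summary: ConsistencySummary

    def accuracy(self, region: str | None = None, config: str = "Full") -> float:
        t = self.occlusion.table
        row = t[t["Config"] == "Full"] if region is None else t[
            (t["Region"] == region.capitalize()) & (t["Config"] == config)
        ]
        return float(row["Accuracy"].iloc[0])


def planted_signal_run(seed: int, params: CohortParams | None = None) -> PlantedRun:
    """One full replicate of the planted-signal explainability study."""
    seed_model, = _subseeds(seed + 7, 1)
    bundle = generate_study(seed, params=params, render=True)
    rf_spec = ModelSpec("random_forest", seed=seed_model, **EXPLAIN_RF)
    occ = occlusion_study(bundle.dataset(aligned=True), rf_spec, bundle.fold_plan)
    importance, _ = fit_importance_forest(bundle, seed_model)
    heat, _, _ = gradcam_heat_profile(bundle, seed_model)
    summary = consistency_summary(
        occlusion_tables={"LDM RF": occ},
        importance_maps={"LDM RF": importance},
        heat_profiles={"DL CNN": heat},
    )
    return PlantedRun(bundle, occ, importance, heat, summary)


def null_calibration_run(seed: int) -> dict[str, CVResult]:
    """No-signal control: effect size 0, RF and MLP under the usual protocol."""
    seed_cohort, seed_model = _subseeds(seed + 13, 2)
    params = CohortParams(effect_size=0.0, seed=seed_cohort)
    bundle = generate_study(seed, params=params, render=False)
    data = bundle.dataset(aligned=True)
    return {
        "random_forest": cross_validate(
            data, ModelSpec("random_forest", seed=seed_model, **EXPLAIN_RF), bundle.fold_plan
        ),
        "mlp": cross_validate(
            data, ModelSpec("mlp", seed=seed_model), bundle.fold_plan
        ),
    }


def comparison_table(
    bundle: StudyBundle,
    combos: list[dict] | None = None,
) -> pd.DataFrame:
    """Approach/Align/Augment/Model comparison rows over one cohort.

    Each combo is a dict with keys ``align`` (bool), ``augment``
    (AugmentParams or None) and ``spec`` (ModelSpec or GridSpec).
    """
    if combos is None:
        seed_model, seed_aug = _subseeds(bundle.params.seed + 29, 2)
        rf = ModelSpec("random_forest", seed=seed_model, **EXPLAIN_RF)
        mlp = ModelSpec("mlp", seed=seed_model)
        aug = AugmentParams(rep=10, magnitude=0.1, seed=seed_aug)
        combos = [
            {"align": a, "augment": g, "spec": s}
            for a in (False, True) for g in (None, aug) for s in (mlp, rf)
        ]
    rows = []
    for combo in combos:
        result = cross_validate(
            bundle.dataset(aligned=combo["align"]),
            combo["spec"], bundle.fold_plan, augment_params=combo.get("augment"),
        )
        rows.append(result.to_row())
    return pd.DataFrame(rows)
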