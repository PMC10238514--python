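"""Explainability battery: occlusion studies, Gini importance, Grad-CAM heat.

Three instruments probe which facial regions drive classification:

* **Occlusion** — retrain/re-evaluate under reveal_only(R) and hide(R)
  configurations, one row per configuration, all rows sharing one fold plan
  and seed so differences are attributable to the occlusion alone.
* **Gini / Mean-Decrease-in-Impurity importance** — per-landmark importance
  of a fitted tree ensemble: the sum of the MDI of the landmark's x and y
  input features, min-max normalized to [0, 1], highlighted at >= 0.5.
* **Saliency heat** — the heat of landmark L on image I is the heatmap value
  at L's pixel; averaged over images, normalized so the hottest landmark
  reads 255, aggregated per region, and expressed as ratios with ears = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVResult, Dataset, FoldPlan, GridSpec, ModelSpec, cross_validate
from .errors import BoundsError, CapabilityError, EmptyFeatureError, TaggingError, ValidationError
from .features import AugmentParams, FeatureTag, occlude_features
from .geometry import RegionBands, mask_image
from .landmarks import LandmarkSet
from .occlusion import OcclusionConfig, standard_configs
from .regions import REGION_NAMES, RegionMap, canonical_region

OCCLUSION_COLUMNS = ["Region", "Config", "Accuracy", "Precision", "Recall"]


@dataclass(frozen=True)
class OcclusionStudy:
    """Per-configuration metrics table plus a ranked reveal/hide summary."""

    table: pd.DataFrame          # OCCLUSION_COLUMNS rows, one per config
    results: dict[str, CVResult]
    failed: tuple[str, ...] = ()

    def _by_region(self, config: str) -> pd.Series:
        sub = self.table[(self.table["Config"] == config) & self.table["Accuracy"].notna()]
        return sub.set_index("Region")["Accuracy"]

    def ranked_summary(self) -> dict[str, str]:
        reveal = self._by_region("Reveal only")
        hide = self._by_region("Hide")
        full = self.table.loc[self.table["Config"] == "Full", "Accuracy"]
        return {
            "reveal_highest": reveal.idxmax(), "reveal_lowest": reveal.idxmin(),
            "hide_highest": hide.idxmax(), "hide_lowest": hide.idxmin(),
            "hide_hurts_most": (float(full.iloc[0]) - hide).idxmax(),
        }


def occlusion_study(
    data: Dataset,
    spec: ModelSpec | GridSpec,
    fold_plan: FoldPlan,
    regions: tuple[str, ...] = REGION_NAMES,
    augment_params: AugmentParams | None = None,
    bands: RegionBands | None = None,
) -> OcclusionStudy:
    """Run full + reveal_only/hide per region under one shared fold plan.

    Landmark datasets are occluded at the feature level (dropping tagged
    vectors); image datasets at the pixel level (band masks, which requires
    ``bands``).  A configuration yielding zero features is recorded as a
    failed row with NaN metrics, never silently skipped.
    """
    image_mode = (spec.family == "cnn_standin") if isinstance(spec, ModelSpec) else False
    if image_mode and bands is None:
        raise ValidationError("image-branch occlusion requires region bands")

    rows, results, failed = [], {}, []
    for config in standard_configs(tuple(canonical_region(r) for r in regions)):
        region_label, config_label = config.label()
        key = f"{region_label}:{config_label}"
        try:
            run = cross_validate(
                _occluded_dataset(data, config, bands, image_mode),
                spec, fold_plan, augment_params=augment_params,
            )
        except EmptyFeatureError:
            failed.append(key)
            rows.append({"Region": region_label, "Config": config_label,
                         "Accuracy": np.nan, "Precision": np.nan, "Recall": np.nan})
            continue
        results[key] = run
        rows.append({"Region": region_label, "Config": config_label,
                     "Accuracy": run.accuracy, "Precision": run.precision,
                     "Recall": run.recall})
    return OcclusionStudy(pd.DataFrame(rows, columns=OCCLUSION_COLUMNS), results, tuple(failed))


def _occluded_dataset(
    data: Dataset, config: OcclusionConfig, bands: RegionBands | None, image_mode: bool
) -> Dataset:
    if image_mode:
        images = np.stack([mask_image(im, bands, config) for im in data.images])
        return Dataset(
            labels=data.labels, subject_ids=data.subject_ids, sets=data.sets,
            images=images, template=data.template,
            approach=data.approach, align_flag=data.align_flag,
        )

    base_featurizer = data._featurize

    def featurizer(sets: list[LandmarkSet]):
        X, tags = base_featurizer(sets)
        return occlude_features(X, tags, config)

    # probe now so zero-feature configs fail before any training
    if data.sets:
        featurizer(data.sets[:1])
    return Dataset(
        labels=data.labels, subject_ids=data.subject_ids, sets=data.sets,
        featurizer=featurizer, template=data.template,
        approach=data.approach, align_flag=data.align_flag,
    )


@dataclass(frozen=True)
class ImportanceMap:
    """Per-landmark MDI importance with normalization and region aggregates."""

    raw: np.ndarray           # (n_landmarks,) nonnegative, sums to ~1
    normalized: np.ndarray    # min-max scaled to [0, 1]
    highlight: np.ndarray     # normalized >= 0.5
    region_map: RegionMap

    def region_means(self) -> dict[str, float]:
        return {
            r: float(self.raw[list(self.region_map.indices(r))].mean())
            for r in self.region_map.regions
        }

    def region_ratios(self) -> dict[str, float]:
        means = self.region_means()
        ears = means["ears"]
        return {r: (m / ears if ears > 0 else np.nan) for r, m in means.items()}


def landmark_importance_mdi(
    forest, tags: list[FeatureTag], region_map: RegionMap | None = None
) -> ImportanceMap:
    """Aggregate a fitted ensemble's MDI feature importances per landmark.

    Each feature's importance is credited to every landmark in its tag (for
    flat coordinates, exactly one).  Untagged features are an error.
    """
    region_map = region_map or RegionMap()
    importances = np.asarray(forest.feature_importances_, float)
    if len(importances) != len(tags):
        raise TaggingError(f"{len(importances)} features but {len(tags)} tags")
    raw = np.zeros(region_map.n_landmarks)
    for imp, tag in zip(importances, tags):
        if not tag.landmarks:
            raise TaggingError(f"feature {tag.name!r} carries no landmark tag")
        for lm in tag.landmarks:
            raw[lm] += imp
    lo, hi = raw.min(), raw.max()
    normalized = (raw - lo) / (hi - lo) if hi > lo else np.ones_like(raw)
    return ImportanceMap(raw, normalized, normalized >= 0.5, region_map)


def gradcam(model, image: np.ndarray, target_class: int) -> np.ndarray:
    """Grad-CAM heatmap for a convolutional model; [0, 1], input frame."""
    if not getattr(model, "is_convolutional", False) or not hasattr(model, "gradcam"):
        raise CapabilityError(
            f"{type(model).__name__} has no convolutional layer to take activations from"
        )
    return model.gradcam(image, target_class)


@dataclass(frozen=True)
class HeatProfile:
    """Average landmark heat on the 0–255 scale with region aggregates."""

    raw: np.ndarray            # per-landmark mean heat before normalization
    scaled: np.ndarray         # raw * 255 / max(raw)
    region_map: RegionMap

    def region_means(self) -> dict[str, float]:
        return {
            r: float(self.scaled[list(self.region_map.indices(r))].mean())
            for r in self.region_map.regions
        }

    def region_ratios(self) -> dict[str, float]:
        means = self.region_means()
        ears = means["ears"]
        return {r: (m / ears if ears > 0 else np.nan) for r, m in means.items()}


def _heat_channel(heatmap: np.ndarray) -> np.ndarray:
    """Scalar heat from a map: RGB rasters use the red channel by convention."""
    heatmap = np.asarray(heatmap, float)
    if heatmap.ndim == 3:
        heatmap = heatmap[..., 0]
    if heatmap.ndim != 2:
        raise ValidationError("heatmap must be (H, W) or (H, W, C)")
    return heatmap


def _pixel(heatmap: np.ndarray, x: float, y: float, image_id: str, lm: int) -> float:
    h, w = heatmap.shape
    col, row = round(float(x)), round(float(y))
    if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
        raise BoundsError(f"image {image_id}: landmark {lm} at ({x:.1f}, {y:.1f}) "
                          f"outside {w}x{h} raster")
    return float(heatmap[min(max(row, 0), h - 1), min(max(col, 0), w - 1)])


def heat_at_landmarks(
    heatmaps: list[np.ndarray],
    landmark_sets: list[LandmarkSet],
    region_map: RegionMap | None = None,
) -> HeatProfile:
    """Heat(L, I) = heatmap value at L's pixel, averaged over images.

    Landmarks map to pixels by nearest-integer rounding (clamped at raster
    edges); the per-landmark averages are normalized by their maximum and
    multiplied by 255, then aggregated per region.
    """
    if len(heatmaps) != len(landmark_sets) or not heatmaps:
        raise ValidationError("need one heatmap per landmark set, at least one pair")
    region_map = region_map or RegionMap()
    n = region_map.n_landmarks
    total = np.zeros(n)
    for hm, s in zip(heatmaps, landmark_sets):
        hm = _heat_channel(hm)
        for lm in range(n):
            total[lm] += _pixel(hm, s.coords[lm, 0], s.coords[lm, 1], s.image_id, lm)
    raw = total / len(heatmaps)
    peak = raw.max()
    scaled = raw * 255.0 / peak if peak > 0 else np.zeros_like(raw)
    return HeatProfile(raw, scaled, region_map)


CONSISTENCY_COLUMNS = ["Approach", "Instrument", "Highest", "Lowest"]

#: Instruments whose highest/lowest pattern must agree for the consensus flag.
_AGREEMENT_INSTRUMENTS = ("Reveal only", "Landmark feature importance", "Landmark average heat")


@dataclass(frozen=True)
class ConsistencySummary:
    table: pd.DataFrame
    agreement: bool
    consensus_highest: str | None
    consensus_lowest: str | None


def consistency_summary(
    occlusion_tables: dict[str, OcclusionStudy] | None = None,
    importance_maps: dict[str, ImportanceMap] | None = None,
    heat_profiles: dict[str, HeatProfile] | None = None,
) -> ConsistencySummary:
    """Cross-instrument highest/lowest region table with an agreement flag.

    The agreement flag holds when every reveal-only, importance and heat row
    names the same highest and the same lowest region (hide rows are shown
    but excluded: their expected pattern is the inverse).
    """
    rows = []
    for name, study in (occlusion_tables or {}).items():
        summary = study.ranked_summary()
        rows.append({"Approach": name, "Instrument": "Reveal only",
                     "Highest": summary["reveal_highest"], "Lowest": summary["reveal_lowest"]})
        rows.append({"Approach": name, "Instrument": "Hide",
                     "Highest": summary["hide_highest"], "Lowest": summary["hide_lowest"]})

    def extremes(values: dict[str, float]) -> tuple[str, str]:
        items = sorted(values.items(), key=lambda kv: kv[1])
        return items[-1][0].capitalize(), items[0][0].capitalize()

    for name, imap in (importance_maps or {}).items():
        hi, lo = extremes(imap.region_means())
        rows.append({"Approach": name, "Instrument": "Landmark feature importance",
                     "Highest": hi, "Lowest": lo})
    for name, profile in (heat_profiles or {}).items():
        hi, lo = extremes(profile.region_means())
        rows.append({"Approach": name, "Instrument": "Landmark average heat",
                     "Highest": hi, "Lowest": lo})
    if not rows:
        raise ValidationError("consistency summary needs at least one completed instrument")

    table = pd.DataFrame(rows, columns=CONSISTENCY_COLUMNS)
    core = table[table["Instrument"].isin(_AGREEMENT_INSTRUMENTS)]
    agreement = bool(len(core)) and core["Highest"].nunique() == 1 and core["Lowest"].nunique() == 1
    return ConsistencySummary(
        table=table,
        agreement=agreement,
        consensus_highest=core["Highest"].iloc[0] if agreement else None,
        consensus_lowest=core["Lowest"].iloc[0] if agreement else None,
    )
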