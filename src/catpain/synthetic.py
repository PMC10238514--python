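"""Synthetic cohort generator with planted, ground-truth facial structure.

The clinical dataset behind the study design (84 client-owned cats scored
with the Glasgow composite measure pain scale) is not public, so every
downstream stage is exercised on simulated cohorts whose signal is planted
and therefore known:

* two classes of 48-landmark configurations that differ by a smooth
  displacement field localized around one facial region ("pain" vs
  "no pain" shape change);
* per-subject similarity perturbations (pose/scale variation between cats)
  and i.i.d. annotation jitter (human landmarking noise);
* CMPS scores sampled inside each class's admissible range, with the
  suspected-pain flag set exactly for the pain class;
* schematic face renders and saliency-style heatmaps for the image branch.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, polygon

from .errors import BoundsError, ParameterError, RegionError
from .landmarks import LandmarkSet
from .regions import RegionMap, canonical_region
from .template import LandmarkTemplate

#: Falloff scale of the radial push inside the effect region, in units of
#: the region's RMS radius.
FIELD_FALLOFF = 1.2

#: Secondary orbital-tightening amplitude: eye landmarks move this fraction
#: of the effect size toward their own eye center.  Compression about each
#: eye's center leaves the eye centers (the alignment anchors) fixed, so the
#: secondary effect is pure shape and cannot leak into other regions through
#: alignment.  Grimace scales pair muzzle tension with orbital tightening,
#: which is the deformation this emulates; ears are left untouched and act
#: as the null region.
EYE_TIGHTENING = 0.08

_BREEDS = [
    ("European short haired cat", 0.55),
    ("British short haired cat", 0.15),
    ("Maine Coone", 0.08),
    ("Norwegian forest cat", 0.04),
    ("Russian blue cat", 0.04),
    ("Ragdoll", 0.03),
    ("Bengal cat", 0.03),
    ("Siamese cat", 0.02),
    ("Birman cat", 0.02),
    ("Sibirian forest cat", 0.02),
    ("British long haired cat", 0.01),
    ("Exotic short haired cat", 0.01),
]
_PAIN_CONDITIONS = [
    "Fracture of the femur", "Pelvic fracture", "FLUTD", "Polytrauma",
    "Avulsion of the tail", "Coprostasis", "Urolithiasis", "Pyometra",
    "Peritonitis", "Trauma after car accident", "Fracture of the humerus",
]
_NO_PAIN_CONDITIONS = [
    "Anemia", "Vomiting", "Seizures", "Pulmonary edema", "Lymphoma",
    "Pneumothorax", "Azotemia", "Lack of appetite", "Corneal ulcer",
    "Pleural effusion", "Foreign body",
]


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for one simulated cohort."""

    n_per_class: int = 42
    effect_region: str = "mouth"
    effect_size: float = 12.0       # px peak displacement on a 256-px canvas
    subject_sd: float = 3.0         # px scale of per-subject pose variation
    annotation_sd: float = 1.5      # px i.i.d. landmarking jitter
    seed: int = 0
    cmps_pain_range: tuple[int, int] = (5, 11)
    cmps_nopain_range: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        if min(self.effect_size, self.subject_sd, self.annotation_sd) < 0:
            raise ParameterError("effect_size and noise scales must be >= 0")
        for lo, hi in (self.cmps_pain_range, self.cmps_nopain_range):
            if not (0 <= lo <= hi <= 20):
                raise ParameterError("CMPS ranges must lie within [0, 20]")
        if self.cmps_nopain_range[1] >= self.cmps_pain_range[0]:
            raise ParameterError("CMPS class ranges must be disjoint")


def displacement_field(template: LandmarkTemplate, effect_region: str) -> np.ndarray:
    """Unit-effect pain displacement field, one (x, y) row per landmark.

    The effect region's landmarks receive a smooth radial push away from the
    region centroid (Gaussian falloff with distance, so the deformation is
    differentiable and sign-stable, with a single scalar amplitude knob).
    When the effect region is not the eyes, the eyes additionally receive an
    attenuated orbital-tightening component — each eye compressed toward its
    own center by ``EYE_TIGHTENING`` of the unit effect — emulating the
    coupled facial-action pattern of grimace scales.  Because compression
    about an eye's center leaves that center fixed, the secondary component
    is invisible to eye-center alignment and cannot contaminate the
    untouched (null) regions.  All other landmarks move by exactly zero.
    """
    region = canonical_region(effect_region)
    idx = list(template.region_map.indices(region))
    center = template.coords[idx].mean(axis=0)
    field = np.zeros_like(template.coords)

    offsets = template.coords[idx] - center
    dist = np.linalg.norm(offsets, axis=1)
    rms = float(np.sqrt(np.mean(dist ** 2)))
    rho = FIELD_FALLOFF * rms
    weight = np.exp(-(dist ** 2) / (2.0 * rho ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(dist[:, None] > 1e-12, offsets / dist[:, None], 0.0)
    field[idx] = weight[:, None] * direction

    if region != "eyes":
        for side in template.region_map.sides("eyes"):
            side = list(side)
            eye_center = template.coords[side].mean(axis=0)
            toward = eye_center - template.coords[side]
            radius = np.linalg.norm(toward, axis=1).mean()
            field[side] = EYE_TIGHTENING * toward / radius
    return field


def _similarity_jitter(rng: np.random.Generator, coords: np.ndarray,
                       center: np.ndarray, sd_px: float, d_io: float) -> np.ndarray:
    """Random subject-level similarity perturbation about the face center."""
    theta = rng.normal(0.0, sd_px / d_io)
    log_s = rng.normal(0.0, sd_px / d_io)
    shift = rng.normal(0.0, sd_px, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return (coords - center) @ (np.exp(log_s) * rot.T) + center + shift


def simulate_cohort(
    template: LandmarkTemplate, params: CohortParams
) -> tuple[pd.DataFrame, list[LandmarkSet]]:
    """Simulate 2*n_per_class subjects: metadata table + one LandmarkSet each.

    The first block is the no-pain class, the second the pain class.  The
    suspected-pain flag is true exactly for pain-class subjects and CMPS
    scores are drawn uniformly from the class's range, so the cohort filters
    downstream reproduce the intended class assignment.
    """
    canonical_region(params.effect_region)  # raises RegionError early
    rng = np.random.default_rng(params.seed)
    field_unit = displacement_field(template, params.effect_region)
    center = np.array(template.canvas_size, dtype=float) / 2.0
    d_io = template.interocular_distance

    breed_names = [b for b, _ in _BREEDS]
    breed_p = np.array([p for _, p in _BREEDS])
    breed_p = breed_p / breed_p.sum()

    records = []
    sets: list[LandmarkSet] = []
    n = params.n_per_class
    for i in range(2 * n):
        painful = i >= n
        sid = f"s{i + 1:03d}"
        coords = template.coords.copy()
        if painful:
            coords = coords + params.effect_size * field_unit
        coords = _similarity_jitter(rng, coords, center, params.subject_sd, d_io)
        coords = coords + rng.normal(0.0, params.annotation_sd, size=coords.shape)
        sets.append(LandmarkSet(image_id=f"img-{sid}", subject_id=sid, coords=coords))

        lo, hi = params.cmps_pain_range if painful else params.cmps_nopain_range
        records.append(
            {
                "subject_id": sid,
                "sex": "m" if rng.random() < 2 / 3 else "f",
                "neutered": bool(rng.random() < 0.8),
                "breed": breed_names[rng.choice(len(breed_names), p=breed_p)],
                "age_months": int(rng.integers(7, 193)),
                "condition": rng.choice(_PAIN_CONDITIONS if painful else _NO_PAIN_CONDITIONS),
                "cmps": int(rng.integers(lo, hi + 1)),
                "pain_suspected": painful,
                "excluded_clinical": False,
            }
        )
    return pd.DataFrame(records), sets


def _angular_order(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    return points[np.argsort(np.arctan2(points[:, 1] - c[1], points[:, 0] - c[0]))]


def render_face(
    landmarks: LandmarkSet | np.ndarray,
    canvas_size: tuple[int, int],
    region_map: RegionMap | None = None,
) -> np.ndarray:
    """Schematic grayscale face render (uint8, shape (height, width)).

    A fixed head disk is drawn as background; ears, eyes and muzzle are
    filled polygons anchored at the landmarks, so pixel content moves with —
    and only with — the landmarks of each region.  Deterministic.
    """
    coords = landmarks.coords if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks, float)
    region_map = region_map or RegionMap()
    width, height = (int(v) for v in canvas_size)
    if (coords[:, 0].min() < 0 or coords[:, 0].max() >= width
            or coords[:, 1].min() < 0 or coords[:, 1].max() >= height):
        raise BoundsError("landmarks outside canvas; cannot render")

    img = np.zeros((height, width), dtype=np.uint8)
    rr, cc = disk((height * 0.55, width * 0.5), 0.47 * min(width, height), shape=img.shape)
    img[rr, cc] = 60

    def fill(points: np.ndarray, value: int) -> None:
        rr, cc = polygon(points[:, 1], points[:, 0], shape=img.shape)
        img[rr, cc] = value

    left, right = region_map.sides("ears")
    fill(coords[list(left)], 150)
    fill(coords[list(right)], 150)
    for side in region_map.sides("eyes"):
        fill(_angular_order(coords[list(side)]), 220)
    fill(_angular_order(coords[list(region_map.indices("mouth"))]), 190)
    return img


def simulate_heatmap(
    landmarks: LandmarkSet | np.ndarray,
    hot_region: str,
    canvas_size: tuple[int, int],
    sigma: float,
    region_map: RegionMap | None = None,
) -> np.ndarray:
    """Saliency-style scalar map in [0, 1]: Gaussian bumps on one region.

    Used as a controllable stand-in for model-attention heatmaps when
    exercising the heat-aggregation operations.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    coords = landmarks.coords if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks, float)
    region_map = region_map or RegionMap()
    idx = list(region_map.indices(hot_region))
    width, height = (int(v) for v in canvas_size)
    ys, xs = np.mgrid[0:height, 0:width]
    heat = np.zeros((height, width), dtype=float)
    for x, y in coords[idx]:
        heat += np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2.0 * sigma ** 2))
    peak = heat.max()
    if peak > 0:
        heat /= peak
    return heat
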