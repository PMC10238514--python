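"""Facial alignment and the horizontal band decomposition used for occlusion.

Alignment is a two-point similarity fit: the similarity transform (scale,
rotation, translation) mapping a set's two eye centers — the mean of each
eye region's landmarks — exactly onto the template's canonical eye-center
targets.  After alignment all eye centers share the same image positions,
which is the property the image-branch band masks rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ParameterError, RegionError, ValidationError
from .landmarks import LandmarkSet
from .occlusion import OcclusionConfig
from .regions import canonical_region
from .template import LandmarkTemplate


@dataclass(frozen=True)
class SimilarityTransform:
    """p -> scale * R(rotation) @ p + translation, in image (x, y) coordinates."""

    scale: float
    rotation: float          # radians, counter-clockwise in (x right, y down)
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError(f"similarity scale must be > 0, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_mat = np.linalg.inv(self.matrix)
        t = -inv_mat @ np.asarray(self.translation)
        return SimilarityTransform(1.0 / self.scale, -self.rotation, (t[0], t[1]))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))


def _as_complex(p: np.ndarray) -> complex:
    return complex(p[0], p[1])


def align_landmarks(
    landmarks: LandmarkSet, template: LandmarkTemplate
) -> tuple[LandmarkSet, SimilarityTransform]:
    """Fit and apply the two-point similarity mapping eye centers onto targets.

    The two-point fit is exact: after alignment the set's eye centers equal
    the template's ``eye_center_targets`` to machine precision.
    """
    centers = template.eye_centers(landmarks.coords)
    targets = template.eye_center_targets
    e1, e2 = (_as_complex(c) for c in centers)
    t1, t2 = (_as_complex(c) for c in targets)
    if abs(e2 - e1) < 1e-9:
        raise DegenerateGeometryError(
            f"image {landmarks.image_id}: coincident eye centers, no similarity fit"
        )
    a = (t2 - t1) / (e2 - e1)
    b = t1 - a * e1
    transform = SimilarityTransform(
        scale=abs(a), rotation=float(np.angle(a)), translation=(b.real, b.imag)
    )
    return landmarks.replace_coords(transform.apply(landmarks.coords)), transform


@dataclass(frozen=True)
class RegionBands:
    """Horizontal tiling of the image height into ears / eyes / mouth bands.

    Integer pixel rows, half-open at the top: ears rows [0, eye_top),
    eyes rows [eye_top, mouth_top), mouth rows [mouth_top, height).  The eye
    band covers every row touched by an eye landmark's y coordinate, so a row
    on the boundary belongs to the lower (larger-y-extent) band.
    """

    eye_top: int     # first row of the eye band
    mouth_top: int   # first row of the mouth band
    height: int

    def __post_init__(self) -> None:
        if not 0 <= self.eye_top <= self.mouth_top <= self.height:
            raise ValidationError(
                f"bands must satisfy 0 <= {self.eye_top} <= {self.mouth_top} <= {self.height}"
            )

    def rows(self, region: str) -> range:
        region = canonical_region(region)
        if region == "ears":
            return range(0, self.eye_top)
        if region == "eyes":
            return range(self.eye_top, self.mouth_top)
        return range(self.mouth_top, self.height)

    def as_dict(self) -> dict[str, list[int]]:
        return {r: [self.rows(r).start, self.rows(r).stop] for r in ("ears", "eyes", "mouth")}


def compute_region_bands(
    aligned_sets: list[LandmarkSet],
    image_height: int,
    template: LandmarkTemplate,
) -> RegionBands:
    """One shared band decomposition for all images of an aligned cohort.

    The eye band spans the minimal to maximal y coordinate of any eye
    landmark over *all* images — general masks rather than per-image masks,
    so no model can read information out of mask placement.
    """
    if not aligned_sets:
        raise ValidationError("cannot compute region bands from an empty cohort")
    eye_idx = list(template.region_map.indices("eyes"))
    ys = np.concatenate([s.coords[eye_idx, 1] for s in aligned_sets])
    y_min, y_max = float(ys.min()), float(ys.max())
    eye_top = int(np.floor(y_min))
    mouth_top = int(np.floor(y_max)) + 1
    if eye_top < 0 or mouth_top > image_height:
        raise ValidationError(
            f"eye landmarks span rows [{eye_top}, {mouth_top}) outside image height {image_height}"
        )
    return RegionBands(eye_top=eye_top, mouth_top=mouth_top, height=image_height)


def mask_image(
    image: np.ndarray,
    bands: RegionBands,
    occlusion: OcclusionConfig,
    fill: int | float = 0,
) -> np.ndarray:
    """Apply a band occlusion: reveal_only keeps one band, hide blanks it.

    The fill value for occluded rows defaults to 0 (black).  Identity for the
    full configuration; output always has the input's shape and dtype.
    """
    if image.shape[0] != bands.height:
        raise ValidationError(
            f"image height {image.shape[0]} inconsistent with bands height {bands.height}"
        )
    out = image.copy()
    if occlusion.mode == "full":
        return out
    region = canonical_region(occlusion.region)
    rows = bands.rows(region)
    if occlusion.mode == "hide":
        out[rows.start:rows.stop] = fill
    elif occlusion.mode == "reveal_only":
        out[: rows.start] = fill
        out[rows.stop:] = fill
    else:
        raise RegionError(f"unknown occlusion mode {occlusion.mode!r}")
    return out
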