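"""Canonical 48-landmark face template.

The published landmark scheme is defined by a drawing, not a coordinate
table, so the package ships a deterministic synthetic template: a bilaterally
symmetric cat-like face laid out in a canonical pixel frame.  It is the
reference pose for alignment, the base shape for the cohort simulator, and
the anchor geometry for rendering.  It is a stand-in for — not a
transcription of — the published scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CanvasSizeError, RegionError
from .regions import RegionMap

MIN_CANVAS = 64

#: Canonical layout constants, expressed in a 256x256 frame and rescaled.
_EAR_PATH = [(70.0, 78.0), (84.0, 20.0), (106.0, 64.0)]  # base-outer, tip, base-inner
_EYE_CENTER = (88.0, 120.0)
_EYE_RADII = (18.0, 10.0)
_MUZZLE_CENTER = (128.0, 190.0)
_MUZZLE_RADII = (42.0, 26.0)
_REF = 256.0


@dataclass(frozen=True)
class LandmarkTemplate:
    """Canonical landmark configuration with its region map and eye targets."""

    coords: np.ndarray            # (48, 2) canonical pixel coordinates
    region_map: RegionMap
    canvas_size: tuple[int, int]  # (width, height) px
    eye_center_targets: np.ndarray  # (2, 2): left then right eye center

    @property
    def interocular_distance(self) -> float:
        left, right = self.eye_center_targets
        return float(np.hypot(*(right - left)))

    def eye_centers(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Mean of each eye's landmarks, left then right, for any coords."""
        coords = self.coords if coords is None else np.asarray(coords, float)
        left, right = self.region_map.sides("eyes")
        return np.stack([coords[list(left)].mean(axis=0), coords[list(right)].mean(axis=0)])


def _sample_polyline(points: list[tuple[float, float]], k: int) -> np.ndarray:
    """k points at even arclength along a polyline."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], k)
    out = np.empty((k, 2))
    for d in range(2):
        out[:, d] = np.interp(t, cum, pts[:, d])
    return out


def _sample_ellipse(center, radii, angles) -> np.ndarray:
    cx, cy = center
    rx, ry = radii
    return np.stack([cx + rx * np.cos(angles), cy + ry * np.sin(angles)], axis=1)


def make_template(
    canvas_size: tuple[int, int] = (256, 256),
    region_counts: dict[str, int] | None = None,
) -> LandmarkTemplate:
    """Build the deterministic symmetric template on the given canvas.

    Parameters
    ----------
    canvas_size
        (width, height) in pixels; at least 64x64.
    region_counts
        Landmarks per region; defaults to ears=10, eyes=14, mouth=24.
        Counts must be even (left/right symmetry) and sum to 48.
    """
    width, height = (int(v) for v in canvas_size)
    if width < MIN_CANVAS or height < MIN_CANVAS:
        raise CanvasSizeError(
            f"canvas {width}x{height} below minimum {MIN_CANVAS}x{MIN_CANVAS}"
        )
    counts = dict(region_counts or {"ears": 10, "eyes": 14, "mouth": 24})
    if sorted(counts) != ["ears", "eyes", "mouth"]:
        raise RegionError(f"region_counts must name exactly ears/eyes/mouth, got {sorted(counts)}")
    if sum(counts.values()) != 48:
        raise RegionError(f"region counts must sum to 48, got {sum(counts.values())}")
    for name, k in counts.items():
        if k < 2 or k % 2:
            raise RegionError(f"region {name!r} needs an even count >= 2, got {k}")

    sx, sy = width / _REF, height / _REF

    def scaled(pts: np.ndarray) -> np.ndarray:
        return pts * np.array([sx, sy])

    def mirrored(pts_left: np.ndarray) -> np.ndarray:
        right = pts_left.copy()
        right[:, 0] = width - right[:, 0]
        return right

    # Ears: polyline base-outer -> tip -> base-inner, one half per side.
    ears_left = scaled(_sample_polyline(_EAR_PATH, counts["ears"] // 2))
    # Eyes: points evenly spaced on an ellipse; their mean is exactly the center.
    k_eye = counts["eyes"] // 2
    eye_angles = 2.0 * np.pi * np.arange(k_eye) / k_eye
    eyes_left = scaled(_sample_ellipse(_EYE_CENTER, _EYE_RADII, eye_angles))
    # Nose/mouth: muzzle ellipse, left half sampled strictly off the midline.
    k_mouth = counts["mouth"] // 2
    mouth_angles = 0.5 * np.pi + np.pi * (np.arange(k_mouth) + 0.5) / k_mouth
    mouth_left = scaled(_sample_ellipse(_MUZZLE_CENTER, _MUZZLE_RADII, mouth_angles))

    coords = np.concatenate(
        [
            ears_left, mirrored(ears_left),
            eyes_left, mirrored(eyes_left),
            mouth_left, mirrored(mouth_left),
        ]
    )
    region_map = RegionMap.from_counts(counts)
    eye_targets = np.array(
        [
            [_EYE_CENTER[0] * sx, _EYE_CENTER[1] * sy],
            [(_REF - _EYE_CENTER[0]) * sx, _EYE_CENTER[1] * sy],
        ]
    )
    return LandmarkTemplate(
        coords=coords,
        region_map=region_map,
        canvas_size=(width, height),
        eye_center_targets=eye_targets,
    )
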