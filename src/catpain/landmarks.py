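"""Landmark containers and their CSV serialization.

One :class:`LandmarkSet` is the atomic observation of the study: the 48
manually annotated (x, y) pixel coordinates of one cat face image, in image
convention (x rightward, y downward, origin at the top-left corner).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ShapeError
from .regions import N_LANDMARKS

LANDMARK_COLUMNS = [
    c for i in range(N_LANDMARKS) for c in (f"x{i}", f"y{i}")
]


@dataclass(frozen=True)
class LandmarkSet:
    """48 (x, y) landmarks of one face image plus its identifiers."""

    image_id: str
    subject_id: str
    coords: np.ndarray  # shape (48, 2), float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (N_LANDMARKS, 2):
            raise ShapeError(
                f"expected {N_LANDMARKS} (x, y) landmarks, got array of shape "
                f"{coords.shape}"
            )
        object.__setattr__(self, "coords", coords)

    def replace_coords(self, coords: np.ndarray, image_id: str | None = None) -> "LandmarkSet":
        return LandmarkSet(image_id or self.image_id, self.subject_id, coords)


def sets_to_frame(sets: list[LandmarkSet]) -> pd.DataFrame:
    """Landmark table with header image_id,subject_id,x0,y0,...,x47,y47."""
    rows = {
        "image_id": [s.image_id for s in sets],
        "subject_id": [s.subject_id for s in sets],
    }
    stack = np.stack([s.coords.reshape(-1) for s in sets]) if sets else np.empty((0, 96))
    for j, col in enumerate(LANDMARK_COLUMNS):
        rows[col] = stack[:, j]
    return pd.DataFrame(rows)


def frame_to_sets(frame: pd.DataFrame) -> list[LandmarkSet]:
    missing = [c for c in ["image_id", "subject_id", *LANDMARK_COLUMNS] if c not in frame.columns]
    if missing:
        raise ShapeError(f"landmark table missing columns {missing[:4]}...")
    coords = frame[LANDMARK_COLUMNS].to_numpy(dtype=float)
    return [
        LandmarkSet(str(img), str(sub), row.reshape(N_LANDMARKS, 2))
        for img, sub, row in zip(frame["image_id"], frame["subject_id"], coords)
    ]


def write_landmarks(sets: list[LandmarkSet], path: str | Path) -> None:
    sets_to_frame(sets).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> list[LandmarkSet]:
    return frame_to_sets(pd.read_csv(path))
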