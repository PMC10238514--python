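"""Model inputs from landmarks: flat coordinates, region vectors, augmentation.

Two feature families are supported, both carrying per-feature tags (region
plus contributing landmark indices) so that occlusion and importance
aggregation operate on tags rather than on column positions:

* flat coordinates — the fixed order x0,y0,...,x47,y47 (96 features), the
  input layer of the perceptron branch and the representation on which
  per-landmark Gini importance is defined;
* multi-region vectors — ordered landmark pairs within each facial region,
  encoded either as endpoint coordinates or as displacement components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

from .errors import EmptyFeatureError, ParameterError, SchemeError, ShapeError
from .landmarks import LandmarkSet
from .occlusion import OcclusionConfig
from .regions import N_LANDMARKS, RegionMap, canonical_region
from .template import LandmarkTemplate


@dataclass(frozen=True)
class FeatureTag:
    """Provenance of one feature column."""

    name: str
    region: str
    landmarks: tuple[int, ...]


@dataclass(frozen=True)
class VectorScheme:
    """Ordered within-region landmark pairs plus the encoding mode.

    ``endpoints`` emits (xi, yi, xj, yj) per pair; ``displacement`` emits
    (xj - xi, yj - yi), which is translation invariant.
    """

    pairs: dict[str, tuple[tuple[int, int], ...]]
    mode: str = "displacement"
    region_map: RegionMap = field(default_factory=RegionMap)

    def __post_init__(self) -> None:
        if self.mode not in ("endpoints", "displacement"):
            raise SchemeError(f"unknown encoding mode {self.mode!r}")
        seen = set()
        for region, pairs in self.pairs.items():
            region = canonical_region(region)
            idx = set(self.region_map.indices(region))
            for pair in pairs:
                if pair in seen:
                    raise SchemeError(f"duplicate pair {pair}")
                seen.add(pair)
                if not set(pair) <= idx:
                    raise SchemeError(
                        f"pair {pair} crosses out of region {region!r}"
                    )

    @property
    def features_per_pair(self) -> int:
        return 4 if self.mode == "endpoints" else 2

    def n_features(self) -> int:
        return self.features_per_pair * sum(len(p) for p in self.pairs.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mode": self.mode,
                       "pairs": {k: [list(p) for p in v] for k, v in self.pairs.items()}},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path, region_map: RegionMap | None = None) -> "VectorScheme":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            pairs={k: tuple(tuple(p) for p in v) for k, v in raw["pairs"].items()},
            mode=raw["mode"],
            region_map=region_map or RegionMap(),
        )


def default_scheme(region_map: RegionMap | None = None, mode: str = "displacement") -> VectorScheme:
    """Consecutive-pair chains within each region, in region-map order."""
    region_map = region_map or RegionMap()
    pairs = {
        region: tuple((idx[i], idx[i + 1]) for i in range(len(idx) - 1))
        for region, idx in region_map.regions.items()
    }
    return VectorScheme(pairs=pairs, mode=mode, region_map=region_map)


def _coords_of(landmarks: LandmarkSet | np.ndarray) -> np.ndarray:
    coords = landmarks.coords if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks, float)
    if coords.shape != (N_LANDMARKS, 2):
        raise ShapeError(f"expected ({N_LANDMARKS}, 2) landmarks, got {coords.shape}")
    return coords


def flatten_coordinates(landmarks: LandmarkSet | np.ndarray) -> np.ndarray:
    """Fixed-order flat vector x0,y0,...,x47,y47 (96 features).

    The landmark order is part of the contract: callers must pass landmarks
    in canonical index order.
    """
    return _coords_of(landmarks).reshape(-1)


def coordinate_tags(region_map: RegionMap | None = None) -> list[FeatureTag]:
    """Tags for the 96 flat coordinates: one landmark, one region each."""
    region_map = region_map or RegionMap()
    tags = []
    for i in range(region_map.n_landmarks):
        region = region_map.region_of(i)
        tags.append(FeatureTag(f"x{i}", region, (i,)))
        tags.append(FeatureTag(f"y{i}", region, (i,)))
    return tags


def build_region_vectors(
    landmarks: LandmarkSet | np.ndarray, scheme: VectorScheme
) -> tuple[np.ndarray, list[FeatureTag]]:
    """Multi-region vector features with per-feature region tags."""
    coords = _coords_of(landmarks)
    values: list[float] = []
    tags: list[FeatureTag] = []
    for region, pairs in scheme.pairs.items():
        region = canonical_region(region)
        for i, j in pairs:
            if scheme.mode == "endpoints":
                values.extend([coords[i, 0], coords[i, 1], coords[j, 0], coords[j, 1]])
                tags.extend(
                    FeatureTag(f"v{i}-{j}:{c}", region, (i, j))
                    for c in ("xi", "yi", "xj", "yj")
                )
            else:
                d = coords[j] - coords[i]
                values.extend([d[0], d[1]])
                tags.extend(
                    FeatureTag(f"v{i}-{j}:{c}", region, (i, j)) for c in ("dx", "dy")
                )
    return np.asarray(values, float), tags


def featurize_sets(
    sets: list[LandmarkSet],
    scheme: VectorScheme | None = None,
    region_map: RegionMap | None = None,
) -> tuple[np.ndarray, list[FeatureTag]]:
    """Feature matrix (n_sets, d) plus shared tags.

    With a scheme, region-vector features; without, flat coordinates.
    """
    if scheme is not None:
        rows = [build_region_vectors(s, scheme) for s in sets]
        return np.stack([r[0] for r in rows]), rows[0][1]
    X = np.stack([flatten_coordinates(s) for s in sets])
    return X, coordinate_tags(region_map)


@dataclass(frozen=True)
class AugmentParams:
    """Jittered-copy augmentation: ``rep`` extra copies per original, each
    coordinate perturbed by uniform noise on [-M d, +M d] with d the set's
    inter-ocular distance (so M is scale free across cats)."""

    rep: int = 10
    magnitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rep < 0:
            raise ParameterError("rep must be >= 0")
        if self.magnitude < 0:
            raise ParameterError("magnitude must be >= 0")

    def describe(self) -> str:
        return "No" if self.rep == 0 else f"Yes(Rep={self.rep}, M={self.magnitude:g})"


def augment(
    sets: list[LandmarkSet],
    params: AugmentParams,
    template: LandmarkTemplate,
) -> list[LandmarkSet]:
    """Each original followed by its ``rep`` jittered copies.

    Copies inherit the source's subject id (and hence label and fold), so
    subject-disjoint splitting keeps every copy with its subject.
    """
    rng = np.random.default_rng(params.seed)
    out: list[LandmarkSet] = []
    for s in sets:
        out.append(s)
        centers = template.eye_centers(s.coords)
        d_io = float(np.hypot(*(centers[1] - centers[0])))
        for k in range(params.rep):
            jitter = rng.uniform(
                -params.magnitude * d_io, params.magnitude * d_io, size=s.coords.shape
            )
            out.append(s.replace_coords(s.coords + jitter, image_id=f"{s.image_id}#aug{k + 1}"))
    return out


def occlude_features(
    X: np.ndarray, tags: list[FeatureTag], occlusion: OcclusionConfig
) -> tuple[np.ndarray, list[FeatureTag]]:
    """Keep (reveal_only) or drop (hide) the features tagged with a region."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[-1] != len(tags):
        raise ShapeError(f"{X.shape[-1]} feature columns but {len(tags)} tags")
    if occlusion.mode == "full":
        return X.copy(), list(tags)
    keep = [
        k for k, t in enumerate(tags)
        if (t.region == occlusion.region) == (occlusion.mode == "reveal_only")
    ]
    if not keep:
        raise EmptyFeatureError(f"occlusion {occlusion} leaves zero features")
    return X[:, keep], [tags[k] for k in keep]
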