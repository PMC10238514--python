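"""Facial region partition of the 48-landmark scheme.

The three regions (ears, eyes, mouth — the latter covering the nose/mouth
area) follow the grimace-scale face parts that motivate region-wise feature
vectors and occlusion.  Which landmark index belongs to which region is data,
not code: a default map ships with the package and any JSON mapping file with
the same structure can replace it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import RegionError

#: Canonical region names, in display order.
REGION_NAMES = ("ears", "eyes", "mouth")

#: Accepted spellings for each canonical region.
_ALIASES = {
    "ears": "ears",
    "ear": "ears",
    "eyes": "eyes",
    "eye": "eyes",
    "mouth": "mouth",
    "nose-mouth": "mouth",
    "nose/mouth": "mouth",
    "nose_mouth": "mouth",
}

N_LANDMARKS = 48


def canonical_region(name: str) -> str:
    """Resolve a region name or alias to its canonical form."""
    try:
        return _ALIASES[str(name).strip().lower()]
    except KeyError:
        raise RegionError(f"unknown facial region {name!r}; known: {REGION_NAMES}") from None


@dataclass(frozen=True)
class RegionMap:
    """Partition of landmark indices 0..n-1 into named facial regions.

    Within each region the index tuple is ordered left side first, then right
    side, each side in anatomical (contour) order; downstream code relies on
    that ordering to split a region into its two sides.
    """

    regions: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(default_region_assignment())
    )

    def __post_init__(self) -> None:
        seen: list[int] = []
        for name, idx in self.regions.items():
            canonical_region(name)
            seen.extend(idx)
        n = len(seen)
        if sorted(seen) != list(range(n)):
            raise RegionError(
                "region map must assign every landmark index to exactly one region"
            )

    @property
    def n_landmarks(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def indices(self, region: str) -> tuple[int, ...]:
        return self.regions[canonical_region(region)]

    def region_of(self, index: int) -> str:
        for name, idx in self.regions.items():
            if index in idx:
                return name
        raise RegionError(f"landmark index {index} not in region map")

    def sides(self, region: str) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Left/right halves of a region, per the ordering contract."""
        idx = self.indices(region)
        half = len(idx) // 2
        return idx[:half], idx[half:]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "RegionMap":
        """Contiguous index blocks in REGION_NAMES order with the given sizes."""
        regions: dict[str, tuple[int, ...]] = {}
        start = 0
        for name in REGION_NAMES:
            k = int(counts[name])
            regions[name] = tuple(range(start, start + k))
            start += k
        return cls(regions)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.regions.items()}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMap":
        raw = json.loads(Path(path).read_text())
        return cls({canonical_region(k): tuple(int(i) for i in v) for k, v in raw.items()})


def default_region_assignment() -> dict[str, tuple[int, ...]]:
    """Default split of the 48 indices: ears 10, eyes 14, nose/mouth 24.

    The published 48-point scheme does not enumerate per-region counts, so
    this split is a documented stand-in (see docs/methods.md).
    """
    return {
        "ears": tuple(range(0, 10)),
        "eyes": tuple(range(10, 24)),
        "mouth": tuple(range(24, 48)),
    }
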