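"""Occlusion configurations shared by the landmark and image branches."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError
from .regions import REGION_NAMES, canonical_region

MODES = ("full", "reveal_only", "hide")


@dataclass(frozen=True)
class OcclusionConfig:
    """One of full / reveal_only(region) / hide(region)."""

    mode: str
    region: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"occlusion mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "full":
            if self.region is not None:
                raise ParameterError("full configuration takes no region")
        else:
            if self.region is None:
                raise ParameterError(f"{self.mode} configuration requires a region")
            object.__setattr__(self, "region", canonical_region(self.region))

    @classmethod
    def full(cls) -> "OcclusionConfig":
        return cls("full")

    @classmethod
    def reveal_only(cls, region: str) -> "OcclusionConfig":
        return cls("reveal_only", region)

    @classmethod
    def hide(cls, region: str) -> "OcclusionConfig":
        return cls("hide", region)

    def label(self) -> tuple[str, str]:
        """(Region, Config) labels in result-table convention."""
        if self.mode == "full":
            return ("All", "Full")
        return (self.region.capitalize(), "Reveal only" if self.mode == "reveal_only" else "Hide")


def standard_configs(regions: tuple[str, ...] = REGION_NAMES) -> list[OcclusionConfig]:
    """Full plus reveal_only/hide per region: 1 + 2 * len(regions) configs."""
    configs = [OcclusionConfig.full()]
    for r in regions:
        configs.append(OcclusionConfig.reveal_only(r))
        configs.append(OcclusionConfig.hide(r))
    return configs
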