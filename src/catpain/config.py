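"""Declarative run configuration for the CLI pipelines.

Every run writes its resolved configuration next to its outputs, so any
artifact is reproducible from the saved YAML plus the seed it records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    # synthetic cohort
    n_per_class: int = 42
    effect_region: str = "mouth"
    effect_size: float = 12.0
    subject_sd: float = 3.0
    annotation_sd: float = 1.5
    canvas: tuple[int, int] = (256, 256)
    # protocol
    k_folds: int = 10
    align: bool = True
    augment_rep: int = 0
    augment_magnitude: float = 0.1
    models: tuple[str, ...] = ("random_forest", "mlp")
    rf_max_depth: int = 20
    rf_n_trees: int = 221
    grid_search: bool = False
    grid_depths: tuple[int, ...] = (1, 5, 10, 20)
    grid_trees: tuple[int, ...] = (61, 121, 221)
    occlusion_regions: tuple[str, ...] = ("ears", "eyes", "mouth")
    region_map_file: str | None = None
    n_render_examples: int = 4

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw = {k: (list(v) if isinstance(v, tuple) else v) for k, v in raw.items()}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        kwargs = {}
        for k, v in raw.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def cohort_params(self):
        from .synthetic import CohortParams

        return CohortParams(
            n_per_class=self.n_per_class,
            effect_region=self.effect_region,
            effect_size=self.effect_size,
            subject_sd=self.subject_sd,
            annotation_sd=self.annotation_sd,
            seed=self.seed,
        )
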