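"""Occlusion studies: landmark branch (RF, MLP) and image branch (CNN).

For each model, trains/tests under the seven configurations (full,
reveal-only and hide per region) with one shared fold plan, so accuracy
differences between rows are attributable to the occlusion alone.  The
landmark branch occludes tagged feature vectors; the image branch masks
the shared horizontal region bands.

Outputs: results/analysis/04_occlusion/occlusion_<model>.csv + summary print.
"""

from pathlib import Path

from catpain import ModelSpec, occlusion_study
from catpain.pipeline import EXPLAIN_RF, generate_study

SEED = 42
OUT = Path("results/analysis/04_occlusion")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = generate_study(SEED)
    specs = {
        "random_forest": ModelSpec("random_forest", seed=SEED, **EXPLAIN_RF),
        "mlp": ModelSpec("mlp", seed=SEED),
        "cnn": ModelSpec("cnn_standin", seed=SEED, cnn_epochs=150),
    }
    for name, spec in specs.items():
        data = bundle.dataset(aligned=True, with_images=spec.family == "cnn_standin")
        study = occlusion_study(data, spec, bundle.fold_plan, bands=bundle.bands)
        study.table.to_csv(OUT / f"occlusion_{name}.csv", index=False)
        summary = study.ranked_summary()
        print(f"\n{name}:")
        print(study.table.to_string(index=False))
        print(f"  reveal-only highest: {summary['reveal_highest']}, "
              f"lowest: {summary['reveal_lowest']}; "
              f"hiding {summary['hide_hurts_most']} hurts most")


if __name__ == "__main__":
    main()
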