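"""Apply the CMPS class rules to the bundled clinical cohort table.

The bundled table transcribes the 84-cat cohort metadata (demographics,
clinical condition, CMPS score, suspected-pain flag).  The class rules —
pain iff CMPS >= 5 with clinical suspicion, no-pain iff CMPS < 4 without,
CMPS = 4 excluded — must reproduce the 42 / 42 split.  Also demonstrates
random undersampling on an imbalanced variant and inter-annotator
reliability (ICC(2,1)) on a synthetically re-annotated image subset.

Outputs under results/analysis/02_cohort/.
"""

from pathlib import Path

import numpy as np

from catpain import assign_classes, balance_undersample, icc2, load_reference_cohort
from catpain.cohort import NO_PAIN, PAIN, write_exclusion_log
from catpain.landmarks import LandmarkSet, sets_to_frame
from catpain.pipeline import generate_study

OUT = Path("results/analysis/02_cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = load_reference_cohort()
    cohort = assign_classes(records)
    cohort.to_frame().to_csv(OUT / "labeled_cohort.csv", index=False)
    write_exclusion_log(cohort, OUT / "exclusions.log")
    print(f"reference cohort: {cohort.class_sizes[PAIN]} pain, "
          f"{cohort.class_sizes[NO_PAIN]} no pain, "
          f"{len(cohort.exclusions)} excluded")

    # undersampling demo: drop 8 pain cats -> rebalance the remainder
    imbalanced = assign_classes(records[:76])
    balanced = balance_undersample(imbalanced, seed=0)
    print(f"after removing 8 subjects: {imbalanced.class_sizes} "
          f"-> undersampled to {balanced.class_sizes}")

    # reliability: a second synthetic annotator re-marks 12 of 84 images
    rng = np.random.default_rng(7)
    bundle = generate_study(7, render=False)
    subset = bundle.sets[:12]
    rater_a = sets_to_frame([
        LandmarkSet(s.image_id, s.subject_id, s.coords + rng.normal(0, 0.8, (48, 2)))
        for s in subset])
    rater_b = sets_to_frame([
        LandmarkSet(s.image_id, s.subject_id, s.coords + rng.normal(0, 0.8, (48, 2)))
        for s in subset])
    result = icc2(rater_a, rater_b)
    result.per_coordinate.to_csv(OUT / "icc2_per_coordinate.csv")
    print(f"ICC(2,1) over 96 coordinates: pooled = {result.pooled:.3f} "
          f"(min {result.per_coordinate.min():.3f})")


if __name__ == "__main__":
    main()
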