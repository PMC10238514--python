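"""Cohort metadata handling: IO, class assignment, balancing, reliability.

The class rules mirror the study protocol for the Glasgow composite measure
pain scale (CMPS-feline, 0–20 points, intervention threshold >= 5):

* ``pain``     — CMPS >= 5 **and** a clinical reason to suspect pain;
* ``no_pain``  — CMPS < 4 **and** no reason to suspect pain;
* excluded     — CMPS exactly 4 (ambiguous band), CMPS >= 5 without clinical
  suspicion, and records carrying a clinical exclusion flag (brachycephalic
  conformation, facial wounds, neurological disease).

"CMPS < 4" is read over integers, so the excluded band is exactly {4}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError, MismatchedImagesError, ValidationError

COHORT_COLUMNS = [
    "subject_id", "sex", "neutered", "breed", "age_months",
    "condition", "cmps", "pain_suspected",
]

PAIN, NO_PAIN = "pain", "no_pain"

_TRUE = {"yes", "true", "1", "y"}
_FALSE = {"no", "false", "0", "n"}


@dataclass(frozen=True)
class CatRecord:
    """Per-subject metadata row of the cohort table."""

    subject_id: str
    sex: str
    neutered: bool
    breed: str
    age_months: int | None
    condition: str
    cmps: int
    pain_suspected: bool
    excluded_clinical: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.cmps <= 20:
            raise ValidationError(
                f"subject {self.subject_id}: cmps={self.cmps} outside [0, 20]"
            )


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValidationError(f"{where}: cannot parse boolean from {value!r}")


def _parse_age(value) -> int | None:
    token = str(value).strip().lower()
    if token in {"", "unknown", "nan", "na", "none"}:
        return None
    return int(token)


def read_cohort(path: str | Path) -> list[CatRecord]:
    """Read a cohort CSV into validated records.

    The optional ``excluded_clinical`` column defaults to False when absent.
    Malformed CMPS values raise :class:`ValidationError` naming the row.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns {missing}")
    records = []
    for i, row in frame.iterrows():
        where = f"row {i + 1} (subject_id={row['subject_id']!r})"
        try:
            cmps = int(str(row["cmps"]).strip())
        except ValueError:
            raise ValidationError(f"{where}: cmps={row['cmps']!r} is not an integer") from None
        try:
            record = CatRecord(
                subject_id=str(row["subject_id"]).strip(),
                sex=str(row["sex"]).strip(),
                neutered=_parse_bool(row["neutered"], where),
                breed=str(row["breed"]).strip(),
                age_months=_parse_age(row["age_months"]),
                condition=str(row["condition"]).strip(),
                cmps=cmps,
                pain_suspected=_parse_bool(row["pain_suspected"], where),
                excluded_clinical=_parse_bool(row["excluded_clinical"], where)
                if "excluded_clinical" in frame.columns and str(row["excluded_clinical"]).strip()
                else False,
            )
        except ValidationError as err:
            raise ValidationError(f"{where}: {err}") from None
        records.append(record)
    return records


def write_cohort(records: list[CatRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS + ["excluded_clinical"])
        for r in records:
            writer.writerow(
                [
                    r.subject_id, r.sex, "Yes" if r.neutered else "No", r.breed,
                    "unknown" if r.age_months is None else r.age_months,
                    r.condition, r.cmps, "Yes" if r.pain_suspected else "No",
                    "Yes" if r.excluded_clinical else "No",
                ]
            )


def records_from_frame(frame: pd.DataFrame) -> list[CatRecord]:
    """Validated records from an in-memory cohort table (same columns as CSV)."""
    return [
        CatRecord(
            subject_id=str(row.subject_id),
            sex=str(row.sex),
            neutered=_parse_bool(row.neutered, f"subject {row.subject_id}"),
            breed=str(row.breed),
            age_months=_parse_age(row.age_months),
            condition=str(row.condition),
            cmps=int(row.cmps),
            pain_suspected=_parse_bool(row.pain_suspected, f"subject {row.subject_id}"),
            excluded_clinical=_parse_bool(getattr(row, "excluded_clinical", False),
                                          f"subject {row.subject_id}"),
        )
        for row in frame.itertuples(index=False)
    ]


def load_reference_cohort() -> list[CatRecord]:
    """Bundled metadata table of the 84-cat clinical cohort (demographics,
    condition, CMPS score, suspected-pain flag)."""
    with resources.as_file(resources.files("catpain.data") / "reference_cohort.csv") as p:
        return read_cohort(p)


@dataclass(frozen=True)
class LabeledCohort:
    """Class-labeled records plus the provenance of every exclusion."""

    records: tuple[CatRecord, ...]
    labels: tuple[str, ...]                      # PAIN / NO_PAIN, parallel to records
    exclusions: tuple[tuple[str, str], ...] = ()  # (subject_id, rule)

    def subset(self, label: str) -> tuple[CatRecord, ...]:
        return tuple(r for r, l in zip(self.records, self.labels) if l == label)

    @property
    def class_sizes(self) -> dict[str, int]:
        return {PAIN: len(self.subset(PAIN)), NO_PAIN: len(self.subset(NO_PAIN))}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**r.__dict__, "label": l} for r, l in zip(self.records, self.labels)
        ]
        return pd.DataFrame(rows)


def assign_classes(records: list[CatRecord]) -> LabeledCohort:
    """Apply the CMPS class rules; every dropped record is logged with its rule.

    Duplicate subject ids are rejected: the design admits one frame per
    individual, so a subject cannot legally appear twice (in either class).
    """
    ids = [r.subject_id for r in records]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValidationError(f"duplicate subject ids {sorted(dupes)}: one frame per individual")

    kept: list[CatRecord] = []
    labels: list[str] = []
    exclusions: list[tuple[str, str]] = []
    for r in records:
        if r.excluded_clinical:
            exclusions.append((r.subject_id, "clinical_exclusion"))
        elif r.cmps == 4:
            exclusions.append((r.subject_id, "cmps_equals_4"))
        elif r.cmps >= 5 and r.pain_suspected:
            kept.append(r)
            labels.append(PAIN)
        elif r.cmps <= 3 and not r.pain_suspected:
            kept.append(r)
            labels.append(NO_PAIN)
        elif r.cmps >= 5:
            exclusions.append((r.subject_id, "high_cmps_without_suspected_pain"))
        else:
            exclusions.append((r.subject_id, "low_cmps_with_suspected_pain"))
    return LabeledCohort(tuple(kept), tuple(labels), tuple(exclusions))


def balance_undersample(cohort: LabeledCohort, seed: int) -> LabeledCohort:
    """Random undersampling of the majority class to the minority size.

    The kept majority subset is drawn uniformly without replacement from the
    seed; the minority class is untouched.  Record order of survivors is
    preserved.
    """
    sizes = cohort.class_sizes
    if min(sizes.values()) == 0:
        raise DegenerateCohortError(f"cannot balance degenerate cohort with sizes {sizes}")
    target = min(sizes.values())
    majority = max(sizes, key=lambda k: sizes[k])
    rng = np.random.default_rng(seed)
    major_pos = [i for i, l in enumerate(cohort.labels) if l == majority]
    keep = set(rng.choice(major_pos, size=target, replace=False).tolist())
    mask = [l != majority or i in keep for i, l in enumerate(cohort.labels)]
    dropped = tuple(
        (cohort.records[i].subject_id, "balancing_undersample")
        for i, m in enumerate(mask) if not m
    )
    return LabeledCohort(
        tuple(r for r, m in zip(cohort.records, mask) if m),
        tuple(l for l, m in zip(cohort.labels, mask) if m),
        cohort.exclusions + dropped,
    )


def write_exclusion_log(cohort: LabeledCohort, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{sid}\t{rule}\n" for sid, rule in cohort.exclusions)
    )


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) per coordinate measurand plus the pooled (mean) summary."""

    per_coordinate: pd.Series
    pooled: float


def icc2(annotator_a: pd.DataFrame, annotator_b: pd.DataFrame) -> ICCResult:
    """Inter-annotator reliability as ICC(2,1) over the 96 XY coordinates.

    Two-way random effects, absolute agreement, single rater.  Inputs are
    landmark tables (as produced by :mod:`catpain.landmarks`) covering the
    same image ids; each of the 96 coordinate columns is one measurand.
    Computed from the classical two-way ANOVA mean squares::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n targets (images) and k = 2 raters.
    """
    a = annotator_a.set_index("image_id").sort_index()
    b = annotator_b.set_index("image_id").sort_index()
    if list(a.index) != list(b.index):
        raise MismatchedImagesError(
            "annotator tables cover different image ids; cannot pair ratings"
        )
    cols = [c for c in a.columns if c[0] in "xy" and c[1:].isdigit()]
    ya = a[cols].to_numpy(float)   # (n_images, 96)
    yb = b[cols].to_numpy(float)
    n, k = ya.shape[0], 2
    if n < 2:
        raise ValidationError("ICC needs at least 2 images")
    y = np.stack([ya, yb], axis=1)                # (n, k, m)
    grand = y.mean(axis=(0, 1))                   # (m,)
    row_mean = y.mean(axis=1)                     # (n, m)
    col_mean = y.mean(axis=0)                     # (k, m)
    msr = k * ((row_mean - grand) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((col_mean - grand) ** 2).sum(axis=0) / (k - 1)
    sst = ((y - grand) ** 2).sum(axis=(0, 1))
    ssr = k * ((row_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((col_mean - grand) ** 2).sum(axis=0)
    sse = sst - ssr - ssc
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msr - mse) / denom, np.nan)
    per = pd.Series(icc, index=cols, name="icc2")
    return ICCResult(per_coordinate=per, pooled=float(np.nanmean(icc)))
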