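import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catpain import (
    CatRecord, assign_classes, balance_undersample, icc2, load_reference_cohort,
    read_cohort, write_cohort,
)
from catpain.cohort import NO_PAIN, PAIN, records_from_frame
from catpain.errors import (
    DegenerateCohortError, MismatchedImagesError, ValidationError,
)
from catpain.landmarks import sets_to_frame


def _record(i, cmps, suspected, excluded=False):
    return CatRecord(subject_id=str(i), sex="m", neutered=True, breed="European short haired cat",
                     age_months=24, condition="Anemia", cmps=cmps,
                     pain_suspected=suspected, excluded_clinical=excluded)


class TestIO:
    def test_round_trip(self, tmp_path, small_cohort):
        _, frame, _ = small_cohort
        records = records_from_frame(frame)
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        assert read_cohort(path) == records

    def test_unknown_age_is_missing(self, tmp_path):
        path = tmp_path / "c.csv"
        write_cohort([CatRecord("1", "f", False, "Ragdoll", None, "Lymphoma", 3, False)], path)
        assert read_cohort(path)[0].age_months is None

    @pytest.mark.parametrize("bad_cmps", ["21", "-1", "3.5", "high"])
    def test_malformed_cmps_names_row(self, tmp_path, bad_cmps):
        path = tmp_path / "c.csv"
        path.write_text(
            "subject_id,sex,neutered,breed,age_months,condition,cmps,pain_suspected\n"
            f"7,m,Yes,Bengal cat,12,Vomiting,{bad_cmps},No\n"
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_cohort(path)

    def test_reference_cohort_has_84_records(self):
        records = load_reference_cohort()
        assert len(records) == 84
        assert len({r.subject_id for r in records}) == 84


class TestAssignClasses:
    def test_rule_filters(self):
        records = [
            _record(1, 7, True),            # pain
            _record(2, 2, False),           # no pain
            _record(3, 4, False),           # CMPS 4 band -> excluded
            _record(4, 9, False),           # high CMPS, no suspicion -> excluded
            _record(5, 1, True),            # low CMPS with suspicion -> excluded
            _record(6, 6, True, True),      # clinical exclusion wins
        ]
        cohort = assign_classes(records)
        assert cohort.class_sizes == {PAIN: 1, NO_PAIN: 1}
        assert dict(cohort.exclusions) == {
            "3": "cmps_equals_4",
            "4": "high_cmps_without_suspected_pain",
            "5": "low_cmps_with_suspected_pain",
            "6": "clinical_exclusion",
        }

    def test_empty_input(self):
        assert assign_classes([]).class_sizes == {PAIN: 0, NO_PAIN: 0}

    def test_duplicate_subject_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            assign_classes([_record(1, 7, True), _record(1, 2, False)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 20), st.booleans(), st.booleans()),
                    max_size=60))
    def test_matches_one_line_rule_oracle(self, rows):
        records = [_record(i, c, s, e) for i, (c, s, e) in enumerate(rows)]
        cohort = assign_classes(records)
        # independent re-statement of the three rules, applied row by row
        expect = {
            r.subject_id: (PAIN if r.cmps >= 5 and r.pain_suspected else NO_PAIN)
            for r in records
            if not r.excluded_clinical and r.cmps != 4
            and ((r.cmps >= 5) == r.pain_suspected)
        }
        got = {r.subject_id: l for r, l in zip(cohort.records, cohort.labels)}
        assert got == expect

    def test_idempotent_and_order_invariant(self):
        records = [_record(i, c, s) for i, (c, s) in
                   enumerate([(7, True), (1, False), (4, False), (11, True), (9, False)])]
        once = assign_classes(records)
        again = assign_classes(list(once.records))
        assert once.records == again.records and once.labels == again.labels
        shuffled = assign_classes(records[::-1])
        assert set(shuffled.records) == set(once.records)


class TestBalance:
    def _cohort(self, n_pain, n_calm):
        records = ([_record(f"p{i}", 8, True) for i in range(n_pain)]
                   + [_record(f"c{i}", 1, False) for i in range(n_calm)])
        return assign_classes(records)

    def test_undersamples_majority_to_minority(self):
        balanced = balance_undersample(self._cohort(42, 60), seed=0)
        assert balanced.class_sizes == {PAIN: 42, NO_PAIN: 42}
        # minority untouched, union of kept + dropped = input
        assert {r.subject_id for r in balanced.subset(PAIN)} == {f"p{i}" for i in range(42)}
        dropped = {s for s, rule in balanced.exclusions if rule == "balancing_undersample"}
        kept = {r.subject_id for r in balanced.records}
        assert kept | dropped == {r.subject_id for r in self._cohort(42, 60).records}

    def test_balanced_input_is_identity(self):
        cohort = self._cohort(5, 5)
        assert balance_undersample(cohort, seed=3).records == cohort.records

    def test_seed_contract(self):
        a = balance_undersample(self._cohort(10, 30), seed=1)
        b = balance_undersample(self._cohort(10, 30), seed=1)
        c = balance_undersample(self._cohort(10, 30), seed=2)
        assert a.records == b.records
        assert a.records != c.records

    def test_empty_class_errors(self):
        with pytest.raises(DegenerateCohortError):
            balance_undersample(self._cohort(0, 5), seed=0)


def _annotation_tables(rng, n_images=6, noise=0.5):
    from catpain import make_template
    from catpain.landmarks import LandmarkSet

    t = make_template()
    base = [t.coords + rng.normal(0, 4, size=(48, 2)) for _ in range(n_images)]
    sets_a = [LandmarkSet(f"img{i}", f"s{i}", c + rng.normal(0, noise, (48, 2)))
              for i, c in enumerate(base)]
    sets_b = [LandmarkSet(f"img{i}", f"s{i}", c + rng.normal(0, noise, (48, 2)))
              for i, c in enumerate(base)]
    return sets_to_frame(sets_a), sets_to_frame(sets_b)


class TestICC:
    def test_identical_raters_give_one(self, rng):
        a, _ = _annotation_tables(rng)
        result = icc2(a, a.copy())
        np.testing.assert_allclose(result.per_coordinate.to_numpy(), 1.0, atol=1e-12)
        assert result.pooled == pytest.approx(1.0)

    def test_constant_offset_penalized(self, rng):
        a, _ = _annotation_tables(rng)
        b = a.copy()
        cols = [c for c in a.columns if c != "image_id" and c != "subject_id"]
        b[cols] = b[cols] + 5.0
        result = icc2(a, b)
        assert (result.per_coordinate < 1.0).all()

    def test_matches_pingouin_variance_components(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = _annotation_tables(rng)
        result = icc2(a, b)
        for col in ["x0", "y17", "x47"]:
            long = pd.DataFrame({
                "targets": list(a["image_id"]) * 2,
                "raters": ["A"] * len(a) + ["B"] * len(b),
                "score": np.concatenate([a[col], b[col]]),
            })
            ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                           ratings="score")
            # absolute-agreement single-rater row, i.e. ICC(2,1)
            expected = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert result.per_coordinate[col] == pytest.approx(expected, abs=1e-10)

    def test_rater_relabeling_invariance(self, rng):
        a, b = _annotation_tables(rng)
        fwd = icc2(a, b)
        rev = icc2(b, a)
        np.testing.assert_allclose(fwd.per_coordinate, rev.per_coordinate, atol=1e-12)

    def test_mismatched_image_ids_error(self, rng):
        a, b = _annotation_tables(rng)
        b = b.iloc[:-1]
        with pytest.raises(MismatchedImagesError):
            icc2(a, b)
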