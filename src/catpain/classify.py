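"""Classifiers under subject-disjoint k-fold cross-validation.

The evaluation protocol is 10-fold cross-validation with no subject overlap:
folds are dealt over *subjects*, and every sample of a subject — including
augmented copies, which inherit their source's subject id — lands in exactly
one fold.  Any subject appearing on both sides of a split is a hard failure,
never a warning.

Model families:

* ``random_forest`` — scikit-learn ensemble; the hyperparameter grid spans
  maximal depth 1..40 and number of trees 1..246 in steps of 5, selected by
  nested (inner) subject-disjoint CV accuracy on the training folds only.
* ``mlp`` — multilayer perceptron over the 96 flat coordinates (or any other
  feature vector), one rectified hidden layer of 64 units by default, with
  input standardization and early stopping.
* ``cnn_standin`` — a small convolutional classifier over rendered images
  (see :mod:`catpain.cnn`); the CV machinery treats it identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import FoldError, LeakageError, ParameterError, ValidationError
from .features import AugmentParams, FeatureTag, augment, featurize_sets
from .landmarks import LandmarkSet
from .template import LandmarkTemplate

FAMILIES = ("random_forest", "mlp", "cnn_standin")

DEPTH_GRID = tuple(range(1, 41))           # MaxDepth 1..40
TREES_GRID = tuple(range(1, 250, 5))       # Trees 1, 6, ..., 246


@dataclass(frozen=True)
class ModelSpec:
    """One concrete model configuration."""

    family: str = "random_forest"
    max_depth: int | None = None
    n_trees: int = 100
    hidden: tuple[int, ...] = (64,)
    seed: int = 0
    cnn_filters: int = 8
    cnn_epochs: int = 250
    cnn_input_size: int = 64

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"model family must be one of {FAMILIES}")

    def describe(self) -> str:
        if self.family == "random_forest":
            return f"RF (Max Depth: {self.max_depth}; Trees: {self.n_trees})"
        if self.family == "mlp":
            return "MLP"
        return "CNN"


@dataclass(frozen=True)
class GridSpec:
    """Exhaustive RF grid searched by inner subject-disjoint CV per outer fold."""

    depth_values: tuple[int, ...] = DEPTH_GRID
    trees_values: tuple[int, ...] = TREES_GRID
    inner_k: int = 3
    seed: int = 0


@dataclass(frozen=True)
class FoldPlan:
    """k disjoint subject groups covering all subjects."""

    folds: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [s for f in self.folds for s in f]
        if len(flat) != len(set(flat)):
            raise FoldError("fold plan assigns some subject to more than one fold")

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def subjects(self) -> set[str]:
        return {s for f in self.folds for s in f}


def make_subject_folds(subject_ids: Sequence[str], k: int, seed: int) -> FoldPlan:
    """Shuffle subjects by seed and deal them into k near-equal folds."""
    subjects = [str(s) for s in subject_ids]
    if len(subjects) != len(set(subjects)):
        raise FoldError("subject ids must be unique")
    if len(subjects) < k:
        raise FoldError(f"cannot make {k} folds from {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    return FoldPlan(tuple(tuple(chunk) for chunk in np.array_split(order, k)))


@dataclass(frozen=True)
class Metrics:
    """Accuracy / precision / recall with the positive class = pain.

    ``precision`` is None (with ``precision_defined`` False) when the model
    made no positive prediction, rather than silently 0.  Recall of a fold
    holding no positive samples is reported as 0 (conservative).
    """

    accuracy: float
    precision: float | None
    recall: float
    precision_defined: bool = True


def evaluate_metrics(y_true, y_pred, positive=1) -> Metrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must be non-empty and equal length")
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    accuracy = float(np.mean(y_pred == y_true))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if tp + fp == 0:
        return Metrics(accuracy, None, recall, precision_defined=False)
    return Metrics(accuracy, tp / (tp + fp), recall)


def build_estimator(spec: ModelSpec):
    if spec.family == "random_forest":
        # class_weight compensates the incidental train-fold imbalance that
        # subject-wise folds induce on a balanced-by-design cohort.
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_depth=spec.max_depth,
            class_weight="balanced", random_state=spec.seed, n_jobs=1,
        )
    if spec.family == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=spec.hidden, activation="relu",
                max_iter=1500, early_stopping=True, n_iter_no_change=25,
                random_state=spec.seed,
            ),
        )
    from .cnn import CnnStandin

    return CnnStandin(
        input_size=spec.cnn_input_size, n_filters=spec.cnn_filters,
        epochs=spec.cnn_epochs, seed=spec.seed,
    )


def grid_search_rf(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence[str],
    depth_values: Sequence[int] = DEPTH_GRID,
    trees_values: Sequence[int] = TREES_GRID,
    inner_seed: int = 0,
    inner_k: int = 3,
) -> tuple[ModelSpec, float]:
    """Exhaustive RF grid by inner subject-disjoint CV accuracy.

    Ties break toward smaller depth, then fewer trees.  Selection never sees
    the outer test fold.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("grid search needs both classes in the training data")
    subjects = np.asarray([str(s) for s in subject_ids])
    plan = make_subject_folds(sorted(set(subjects)), inner_k, inner_seed)
    splits = []
    for fold in plan.folds:
        test = np.isin(subjects, list(fold))
        if len(np.unique(y[~test])) < 2 or not test.any():
            continue
        splits.append(test)
    if not splits:
        raise ValidationError("inner folds degenerate; cannot grid search")

    best: tuple[float, ModelSpec] | None = None
    for depth in sorted(depth_values):
        for trees in sorted(trees_values):
            spec = ModelSpec("random_forest", max_depth=depth, n_trees=trees, seed=inner_seed)
            accs = []
            for test in splits:
                est = build_estimator(spec)
                est.fit(X[~test], y[~test])
                accs.append(float(np.mean(est.predict(X[test]) == y[test])))
            score = float(np.mean(accs))
            if best is None or score > best[0]:
                best = (score, spec)
    return best[1], best[0]


@dataclass(frozen=True)
class CVResult:
    """One metrics row of the comparison table plus its per-fold detail."""

    approach: str
    align: str
    augment: str
    model: str
    accuracy: float
    precision: float | None
    recall: float
    fold_metrics: tuple[Metrics, ...] = ()
    chosen_specs: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {
            "Approach": self.approach, "Align": self.align, "Augment": self.augment,
            "Model": self.model, "Accuracy": round(self.accuracy, 4),
            "Precision": None if self.precision is None else round(self.precision, 4),
            "Recall": round(self.recall, 4),
        }

    @property
    def fold_accuracy_se(self) -> float:
        accs = np.array([m.accuracy for m in self.fold_metrics])
        return float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0


@dataclass
class Dataset:
    """Samples for cross-validation: landmarks and/or images, labels, subjects.

    ``featurizer`` maps a list of landmark sets to (X, tags); when None the
    flat 96-coordinate representation is used.  Images are a (n, H, W) float
    stack aligned with ``sets`` order, consumed by the cnn_standin family.
    """

    labels: np.ndarray
    subject_ids: np.ndarray
    sets: list[LandmarkSet] | None = None
    images: np.ndarray | None = None
    featurizer: Callable[[list[LandmarkSet]], tuple[np.ndarray, list[FeatureTag]]] | None = None
    template: LandmarkTemplate | None = None
    approach: str = "LDM"
    align_flag: str = "No"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        self.subject_ids = np.asarray([str(s) for s in self.subject_ids])
        if self.labels.shape != self.subject_ids.shape:
            raise ValidationError("labels and subject_ids must be parallel")

    def label_of(self) -> dict[str, int]:
        return {s: int(l) for s, l in zip(self.subject_ids, self.labels)}

    def _featurize(self, sets: list[LandmarkSet]) -> tuple[np.ndarray, list[FeatureTag]]:
        if self.featurizer is not None:
            return self.featurizer(sets)
        region_map = self.template.region_map if self.template else None
        return featurize_sets(sets, None, region_map)


def _assert_no_leakage(train_subjects: set[str], test_subjects: set[str]) -> None:
    overlap = train_subjects & test_subjects
    if overlap:
        raise LeakageError(f"subjects {sorted(overlap)[:5]} appear in train and test")


def cross_validate(
    data: Dataset,
    spec_or_grid: ModelSpec | GridSpec,
    fold_plan: FoldPlan,
    augment_params: AugmentParams | None = None,
) -> CVResult:
    """Per-fold fit/predict with metrics averaged (unweighted) over folds.

    Augmentation, when requested, is applied to the training folds only, on
    landmarks, before feature extraction; augmented copies keep their
    subject id so subject disjointness is preserved by construction — and
    asserted anyway.
    """
    is_grid = isinstance(spec_or_grid, GridSpec)
    family = "random_forest" if is_grid else spec_or_grid.family
    if family == "cnn_standin" and augment_params is not None and augment_params.rep:
        raise ParameterError("landmark-jitter augmentation applies to the landmark branch only")

    label_of = data.label_of()
    fold_metrics: list[Metrics] = []
    chosen: list[str] = []
    for fold in fold_plan.folds:
        test_subjects = set(fold)
        test_mask = np.isin(data.subject_ids, list(test_subjects))
        if not test_mask.any():
            continue
        train_subjects = set(data.subject_ids[~test_mask])
        _assert_no_leakage(train_subjects, test_subjects)

        if family == "cnn_standin":
            if data.images is None:
                raise ValidationError("cnn_standin requires images in the dataset")
            X_train, X_test = data.images[~test_mask], data.images[test_mask]
            y_train, y_test = data.labels[~test_mask], data.labels[test_mask]
            spec = spec_or_grid
        else:
            train_sets = [s for s, m in zip(data.sets, test_mask) if not m]
            test_sets = [s for s, m in zip(data.sets, test_mask) if m]
            if augment_params is not None and augment_params.rep:
                train_sets = augment(train_sets, augment_params, data.template)
                _assert_no_leakage({s.subject_id for s in train_sets}, test_subjects)
            y_train = np.array([label_of[s.subject_id] for s in train_sets])
            y_test = np.array([label_of[s.subject_id] for s in test_sets])
            X_train, _ = data._featurize(train_sets)
            X_test, _ = data._featurize(test_sets)
            if is_grid:
                spec, _ = grid_search_rf(
                    X_train, y_train, [s.subject_id for s in train_sets],
                    spec_or_grid.depth_values, spec_or_grid.trees_values,
                    inner_seed=spec_or_grid.seed, inner_k=spec_or_grid.inner_k,
                )
            else:
                spec = spec_or_grid

        est = build_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X_train, y_train)
        fold_metrics.append(evaluate_metrics(y_test, est.predict(X_test)))
        chosen.append(spec.describe())

    accuracy = float(np.mean([m.accuracy for m in fold_metrics]))
    recall = float(np.mean([m.recall for m in fold_metrics]))
    defined = [m.precision for m in fold_metrics if m.precision_defined]
    precision = float(np.mean(defined)) if defined else None
    model_label = chosen[0] if len(set(chosen)) == 1 else f"{family} (per-fold selection)"
    return CVResult(
        approach=data.approach,
        align=data.align_flag,
        augment=augment_params.describe() if augment_params else "No",
        model=model_label,
        accuracy=accuracy, precision=precision, recall=recall,
        fold_metrics=tuple(fold_metrics), chosen_specs=tuple(chosen),
    )
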