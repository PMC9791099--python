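"""Leakage-proof k-fold cross-validation over three probabilistic classifiers.

Within each fold, feature ranking, top-k selection and standardization
statistics are derived from the training rows only; the held-out rows are
scored and their class-1 probabilities pooled so that every sample is a test
sample exactly once per classifier.

Classifier families (names are part of the public contract):

* ``sparse_logistic_regression`` — L1-penalized logistic regression.
* ``support_vector_machine`` — linear-kernel SVM with Platt probability
  calibration.
* ``gaussian_process`` — RBF-kernel GP classifier with a fixed length scale
  set by the median pairwise training distance (no hyperparameter search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .errors import FoldDegenerateError, FoldPlanError, InvalidLabelsError
from .selection import rank_features, select_top_k

__all__ = [
    "CLASSIFIER_NAMES",
    "FoldPlan",
    "ClassifierSpec",
    "CVResult",
    "make_folds",
    "fit_predict_fold",
    "run_cv",
    "run_cv_global_selection",
]

CLASSIFIER_NAMES = (
    "sparse_logistic_regression",
    "support_vector_machine",
    "gaussian_process",
)


@dataclass(frozen=True)
class FoldPlan:
    """Per-sample fold assignment for one CV run."""

    assignment: np.ndarray  # fold id per sample, in 0..n_folds-1
    n_folds: int
    seed: int
    stratified: bool

    def train_test(self, fold_id: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold_id)
        train = np.flatnonzero(self.assignment != fold_id)
        return train, test


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise InvalidLabelsError(
                f"unknown classifier {self.name!r}; expected one of {CLASSIFIER_NAMES}"
            )


DEFAULT_SPECS = tuple(ClassifierSpec(name) for name in CLASSIFIER_NAMES)


@dataclass
class CVResult:
    """Pooled out-of-fold probabilities plus per-fold audit information."""

    probabilities: dict[str, np.ndarray]  # classifier name -> class-1 prob per sample
    fold_selected: list[np.ndarray]  # per fold: selected feature indices
    labels: np.ndarray
    fold_plan: FoldPlan
    config: dict

    def to_dict(self) -> dict:
        return {
            "probabilities": {k: v.tolist() for k, v in self.probabilities.items()},
            "fold_selected": [s.tolist() for s in self.fold_selected],
            "labels": self.labels.tolist(),
            "fold_assignment": self.fold_plan.assignment.tolist(),
            "config": self.config,
        }


def make_folds(labels, n_folds: int, seed: int, stratified: bool = True) -> FoldPlan:
    """Deterministic (seeded) fold assignment with balanced fold sizes."""
    labels = np.asarray(labels)
    n = labels.size
    if n_folds < 2:
        raise FoldPlanError("n_folds must be >= 2")
    if n < n_folds:
        raise FoldPlanError(f"{n} samples cannot fill {n_folds} folds")
    assignment = np.empty(n, dtype=int)
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.size < 2:
            raise FoldPlanError("stratification requires at least two classes")
        if counts.min() < n_folds:
            raise FoldPlanError(
                f"smallest class has {counts.min()} members; "
                f"stratified {n_folds}-fold CV needs at least {n_folds}"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)), labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)))
    for fold_id, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold_id
    return FoldPlan(assignment=assignment, n_folds=n_folds, seed=seed, stratified=stratified)


def _median_heuristic_length_scale(X: np.ndarray) -> float:
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def _build_estimator(spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.name == "sparse_logistic_regression":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=hp.get("C", 1.0), max_iter=1000,
            random_state=seed,
        )
    if spec.name == "support_vector_machine":
        # Platt-type sigmoid calibration on training data only
        min_class = int(np.unique(y_train, return_counts=True)[1].min())
        cv = max(2, min(3, min_class))
        return CalibratedClassifierCV(
            SVC(kernel="linear", C=hp.get("C", 1.0), random_state=seed),
            method="sigmoid",
            ensemble=False,
            cv=cv,
        )
    if spec.name == "gaussian_process":
        ls = hp.get("length_scale") or _median_heuristic_length_scale(X_train)
        return GaussianProcessClassifier(
            kernel=RBF(length_scale=ls), optimizer=None, random_state=seed
        )
    raise InvalidLabelsError(f"unknown classifier {spec.name!r}")


def fit_predict_fold(
    matrix,
    labels,
    fold_plan: FoldPlan,
    fold_id: int,
    spec: ClassifierSpec,
    k: int,
    selected: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank/select/standardize/fit on training rows only; score test rows.

    Returns ``(test_probabilities, selected_feature_indices)``.  ``selected``
    may be supplied to reuse a ranking already computed for this fold (it
    must itself have been derived from the fold's training rows).
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    train, test = fold_plan.train_test(fold_id)
    y_train = y[train]
    classes = np.unique(y_train)
    if classes.size < 2:
        raise FoldDegenerateError(f"fold {fold_id}: training portion has one class")
    if selected is None:
        pvalues = rank_features(X[train], y_train)
        selected = select_top_k(pvalues, k)
    X_train = X[np.ix_(train, selected)]
    X_test = X[np.ix_(test, selected)]
    # fold-local standardization: test rows scaled by training statistics
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    X_train = (X_train - mu) / sd
    X_test = (X_test - mu) / sd
    y01 = (y_train == classes[1]).astype(int)
    est = _build_estimator(spec, X_train, y01, seed=fold_plan.seed)
    est.fit(X_train, y01)
    probs = est.predict_proba(X_test)[:, list(est.classes_).index(1)]
    return np.clip(probs, 0.0, 1.0), np.asarray(selected)


def run_cv(
    matrix,
    labels,
    specs: Sequence[ClassifierSpec] = DEFAULT_SPECS,
    n_folds: int = 10,
    k: int = 100,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """Full cross-validation: pooled out-of-fold probabilities per classifier."""
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise InvalidLabelsError("matrix rows must match labels")
    plan = make_folds(y, n_folds=n_folds, seed=seed, stratified=stratified)
    probabilities = {spec.name: np.full(y.size, np.nan) for spec in specs}
    fold_selected: list[np.ndarray] = []
    for fold_id in range(n_folds):
        train, test = plan.train_test(fold_id)
        if test.size == 0:
            fold_selected.append(np.array([], dtype=int))
            continue
        y_train = y[train]
        if np.unique(y_train).size < 2:
            raise FoldDegenerateError(
                f"fold {fold_id}: training portion has a single class"
            )
        pvalues = rank_features(X[train], y_train)
        selected = select_top_k(pvalues, k)
        fold_selected.append(selected)
        for spec in specs:
            probs, _ = fit_predict_fold(X, y, plan, fold_id, spec, k, selected=selected)
            probabilities[spec.name][test] = probs
    for name, p in probabilities.items():
        if np.isnan(p).any():
            raise FoldPlanError(f"{name}: some samples were never scored")
    config = {
        "n_folds": n_folds,
        "k": int(k),
        "seed": int(seed),
        "stratified": bool(stratified),
        "classifiers": [spec.name for spec in specs],
    }
    return CVResult(
        probabilities=probabilities,
        fold_selected=fold_selected,
        labels=y.copy(),
        fold_plan=plan,
        config=config,
    )


def run_cv_global_selection(
    matrix,
    labels,
    specs: Sequence[ClassifierSpec] = DEFAULT_SPECS,
    n_folds: int = 10,
    k: int = 100,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """Deliberately leaky variant for diagnostics: select features once on the
    FULL data set before cross-validation.

    This reproduces the classic selection-leakage mistake and exists only to
    demonstrate, on null data, how much it inflates apparent performance
    relative to :func:`run_cv`.  Never use it for reported results.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    pvalues = rank_features(X, y)
    selected = select_top_k(pvalues, k)
    plan = make_folds(y, n_folds=n_folds, seed=seed, stratified=stratified)
    probabilities = {spec.name: np.full(y.size, np.nan) for spec in specs}
    for fold_id in range(n_folds):
        _, test = plan.train_test(fold_id)
        for spec in specs:
            probs, _ = fit_predict_fold(X, y, plan, fold_id, spec, k, selected=selected)
            probabilities[spec.name][test] = probs
    config = {
        "n_folds": n_folds,
        "k": int(k),
        "seed": int(seed),
        "stratified": bool(stratified),
        "classifiers": [spec.name for spec in specs],
        "leaky_global_selection": True,
    }
    return CVResult(
        probabilities=probabilities,
        fold_selected=[np.asarray(selected)] * n_folds,
        labels=y.copy(),
        fold_plan=plan,
        config=config,
    )
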