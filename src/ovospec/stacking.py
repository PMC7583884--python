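"""Two-layer stacked generalization with out-of-fold meta-features.

The first layer is the three classifier kinds that achieved the best grid
accuracy; each contributes a block of class probabilities.  Training-row
meta-features come from the fold model that never saw the row (five
stratified folds), test-row meta-features are the average of the five fold
models' probabilities — the standard leak-free construction.  The second
layer (default: linear Gaussian discriminant, DAC) is fitted on the
meta-feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import (ClassifierSpec, GridResult, _fit_with_shrinkage,
                       make_classifier, train_and_eval)
from .freshness import GRADES


@dataclass
class MetaFeatures:
    """Per-base class-probability blocks for train (OOF) and test rows."""

    M_train: np.ndarray
    M_test: np.ndarray
    classes: tuple
    fold_assignment: np.ndarray
    fold_models: list  # per base: list of 5 fitted fold models


def select_top_bases(grid_results: Sequence[GridResult],
                     k: int = 3) -> list[GridResult]:
    """Best pipeline of each of the top-k classifier kinds by test accuracy.

    One pipeline per kind; kinds ranked by their best achieved test accuracy
    (ties: training accuracy, then lexicographic pipeline id).
    """
    best_per_kind: dict[str, GridResult] = {}
    for r in grid_results:
        if not r.ok:
            continue
        cur = best_per_kind.get(r.classifier)
        key = lambda g: (-g.test_accuracy, -g.train_accuracy, g.pipeline_id)
        if cur is None or key(r) < key(cur):
            best_per_kind[r.classifier] = r
    if len(best_per_kind) < k:
        raise ValueError(
            f"need at least {k} distinct classifier kinds, "
            f"got {len(best_per_kind)}")
    ranked = sorted(best_per_kind.values(),
                    key=lambda g: (-g.test_accuracy, -g.train_accuracy,
                                   g.pipeline_id))
    return ranked[:k]


def _proba_in_class_order(model, X: np.ndarray, classes: tuple) -> np.ndarray:
    """predict_proba re-ordered to the global class order (absent → 0)."""
    p = model.predict_proba(X)
    out = np.zeros((X.shape[0], len(classes)))
    for j, c in enumerate(model.classes_):
        out[:, classes.index(c)] = p[:, j]
    return out


def oof_meta_features(base_specs: Sequence[ClassifierSpec], X_train, y_train,
                      X_test, folds: int = 5, seed: int = 0,
                      classes: Sequence = GRADES,
                      hard_labels: bool = False,
                      precomputed_folds=None) -> MetaFeatures:
    """Out-of-fold meta-features for a list of base classifiers.

    Each training row's block comes from the fold model not trained on that
    row; each test row's block is the mean over the ``folds`` fold models.
    With ``hard_labels`` the probability blocks are replaced by one-hot
    predictions.  ``precomputed_folds`` (a sample → fold-index array, e.g. a
    previous run's ``fold_assignment``) pins the fold geometry, which would
    otherwise be re-stratified from the labels.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    n = y_train.size
    if n < folds:
        raise ValueError("need at least as many training rows as folds")
    classes = tuple(classes)

    if precomputed_folds is not None:
        assignment = np.asarray(precomputed_folds, dtype=int)
        if assignment.shape != (n,):
            raise ValueError("precomputed fold assignment length mismatch")
        fold_pairs = [(np.nonzero(assignment != f)[0],
                       np.nonzero(assignment == f)[0])
                      for f in range(folds)]
    else:
        counts = np.unique(y_train, return_counts=True)[1]
        if counts.min() < folds:
            raise ValueError(
                "stratified folding impossible: a class has fewer samples "
                f"({counts.min()}) than folds ({folds})")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_pairs = list(skf.split(X_train, y_train))
        assignment = np.empty(n, dtype=int)
        for f, (_, va) in enumerate(fold_pairs):
            assignment[va] = f

    n_cls = len(classes)
    M_train = np.zeros((n, len(base_specs) * n_cls))
    M_test = np.zeros((X_test.shape[0], len(base_specs) * n_cls))
    all_models: list[list] = []
    for b, spec in enumerate(base_specs):
        block = slice(b * n_cls, (b + 1) * n_cls)
        fold_models = []
        test_acc = np.zeros((X_test.shape[0], n_cls))
        for tr, va in fold_pairs:
            model = _fit_with_shrinkage(spec, make_classifier(spec),
                                        X_train[tr], y_train[tr])
            fold_models.append(model)
            p_va = _proba_in_class_order(model, X_train[va], classes)
            p_te = _proba_in_class_order(model, X_test, classes)
            if hard_labels:
                p_va = _one_hot(np.argmax(p_va, axis=1), n_cls)
                p_te = _one_hot(np.argmax(p_te, axis=1), n_cls)
            M_train[va, block] = p_va
            test_acc += p_te
        M_test[:, block] = test_acc / folds
        all_models.append(fold_models)
    return MetaFeatures(M_train, M_test, classes, assignment, all_models)


def _one_hot(idx: np.ndarray, n_cls: int) -> np.ndarray:
    out = np.zeros((idx.size, n_cls))
    out[np.arange(idx.size), idx] = 1.0
    return out


def stack_fit_predict(meta_spec: ClassifierSpec, M_train, y_train, M_test,
                      y_test) -> GridResult:
    """Fit the second-layer classifier on meta-features and evaluate."""
    if np.asarray(M_train).shape[1] != np.asarray(M_test).shape[1]:
        raise ValueError("train/test meta-feature widths differ")
    return train_and_eval(meta_spec, M_train, y_train, M_test, y_test)


@dataclass
class StackingModel:
    """A fitted two-layer stack (for reuse/prediction on new spectra)."""

    base_specs: list
    meta_spec: ClassifierSpec
    meta_features: MetaFeatures
    meta_model: object
    result: GridResult


def stack_pipeline(base_specs: Sequence[ClassifierSpec], X_train, y_train,
                   X_test, y_test, meta_spec: Optional[ClassifierSpec] = None,
                   folds: int = 5, seed: int = 0) -> StackingModel:
    """Convenience: OOF meta-features + second-layer fit + evaluation."""
    meta_spec = meta_spec or ClassifierSpec.make("DAC", seed=seed)
    mf = oof_meta_features(base_specs, X_train, y_train, X_test,
                           folds=folds, seed=seed)
    result = stack_fit_predict(meta_spec, mf.M_train, y_train,
                               mf.M_test, y_test)
    return StackingModel(list(base_specs), meta_spec, mf, result.model, result)
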