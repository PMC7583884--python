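"""Weak classifiers, the stratified 71.43/28.57 split, and the model grid.

Six classifier kinds behind one spec: SVM (RBF), KNN, random forest,
Gaussian naive Bayes, DAC (Gaussian discriminant analysis, linear pooled
covariance by default or quadratic per-class), and LDA as a Fisher
discriminant projection followed by a nearest-centroid rule.  All expose
class probabilities so any of them can feed the stacked ensemble.

``run_grid`` sweeps preprocessing × wavelength selection × classifier per
acquisition mode, fitting every stage on the training rows only, and reports
the best pipeline per mode by test accuracy (ties: higher training accuracy,
then lexicographic pipeline id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .freshness import GRADES, grade_code
from .preprocess import Preprocessor, SpectraMatrix
from .select import SelectionResult, cars_select, pca_reduce, spa_select

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("SVM", "KNN", "RF", "NB", "DAC", "LDA")
SELECTORS = ("pca", "spa", "cars")


class FisherLDAClassifier(BaseEstimator, ClassifierMixin):
    """Fisher discriminant projection + nearest class centroid.

    Probabilities are a softmax over negative squared distances to the
    centroids in the projected space.
    """

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_comp = min(len(self.classes_) - 1, X.shape[1])
        self._proj = LinearDiscriminantAnalysis(n_components=n_comp)
        Z = self._proj.fit_transform(X, y)
        self._centroids = np.vstack(
            [Z[y == c].mean(axis=0) for c in self.classes_])
        return self

    def _dist2(self, X):
        Z = self._proj.transform(X)
        return ((Z[:, None, :] - self._centroids[None, :, :]) ** 2).sum(axis=2)

    def predict(self, X):
        return self.classes_[np.argmin(self._dist2(X), axis=1)]

    def predict_proba(self, X):
        logits = -0.5 * self._dist2(X)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind with hyperparameters and a seed."""

    kind: str
    hyperparams: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        params = dict(self.hyperparams)
        allowed = {"SVM": {"C", "gamma", "kernel"},
                   "KNN": {"k"},
                   "RF": {"n_trees"},
                   "NB": set(),
                   "DAC": {"discriminant"},
                   "LDA": set()}[self.kind]
        extra = set(params) - allowed
        if extra:
            raise ValueError(
                f"invalid hyperparameters for {self.kind}: {sorted(extra)}")
        if params.get("discriminant", "linear") not in ("linear", "quadratic"):
            raise ValueError("DAC discriminant must be linear or quadratic")

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    @classmethod
    def make(cls, kind: str, seed: int = 0, **params) -> "ClassifierSpec":
        return cls(kind=kind, hyperparams=tuple(sorted(params.items())),
                   seed=seed)


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn-compatible estimator for a spec."""
    p = spec.params
    if spec.kind == "SVM":
        return SVC(kernel=p.get("kernel", "rbf"), C=p.get("C", 1.0),
                   gamma=p.get("gamma", "scale"), probability=True,
                   random_state=spec.seed)
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=p.get("k", 5))
    if spec.kind == "RF":
        return RandomForestClassifier(n_estimators=p.get("n_trees", 100),
                                      random_state=spec.seed)
    if spec.kind == "NB":
        return GaussianNB()
    if spec.kind == "DAC":
        if p.get("discriminant", "linear") == "quadratic":
            return QuadraticDiscriminantAnalysis()
        return LinearDiscriminantAnalysis()
    return FisherLDAClassifier()


def _fit_with_shrinkage(spec: ClassifierSpec, model, X, y):
    """Fit; on a singular discriminant covariance retry with shrinkage."""
    try:
        model.fit(X, y)
        return model
    except np.linalg.LinAlgError:
        if spec.kind != "DAC":
            raise
        logger.warning("DAC covariance singular; refitting with shrinkage")
        if isinstance(model, QuadraticDiscriminantAnalysis):
            model = QuadraticDiscriminantAnalysis(reg_param=1e-3)
        else:
            model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        model.fit(X, y)
        return model


def stratified_split(y, train_fraction: float = 0.7143,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; training size rounds to nearest per class.

    Returns (train_indices, test_indices), disjoint and exhaustive.
    """
    y = np.asarray(y)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_tr = int(round(train_fraction * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.append(perm[:n_tr])
        test.append(perm[n_tr:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class GridResult:
    """One (mode × preprocessor × selector × classifier) grid cell."""

    mode: str
    preprocessor: str
    selector: str
    classifier: str
    train_accuracy: float
    test_accuracy: float
    confusion: np.ndarray
    n_train: int
    n_test: int
    selection: Optional[SelectionResult] = None
    model: object = None
    error: Optional[str] = None

    @property
    def pipeline_id(self) -> str:
        return f"{self.preprocessor}-{self.selector}-{self.classifier}"

    @property
    def ok(self) -> bool:
        return self.error is None


def train_and_eval(spec: ClassifierSpec, X_train, y_train, X_test, y_test,
                   classes: Sequence = GRADES) -> GridResult:
    """Fit one classifier and evaluate accuracy/confusion on both sets."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(X_test))):
        raise ValueError("features must be finite")
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = _fit_with_shrinkage(spec, make_classifier(spec), X_train, y_train)
    pred_tr = model.predict(X_train)
    pred_te = model.predict(X_test)
    labels = [c for c in classes]
    return GridResult(
        mode="", preprocessor="", selector="", classifier=spec.kind,
        train_accuracy=float(np.mean(pred_tr == y_train)),
        test_accuracy=float(np.mean(pred_te == y_test)),
        confusion=confusion_matrix(y_test, pred_te, labels=labels),
        n_train=int(y_train.size), n_test=int(y_test.size), model=model)


def _select_features(selector: str, X_tr: np.ndarray, X_te: np.ndarray,
                     y_tr_code: np.ndarray, seed: int,
                     params: Optional[dict] = None):
    """Fit a selector on training data; return (features_tr, features_te, res)."""
    params = dict(params or {})
    if selector == "pca":
        res = pca_reduce(X_tr, X_te, n_components=params.get("n_components", 3))
        return res.projected_train, res.projected_test, res
    if selector == "spa":
        res = spa_select(X_tr, y_tr_code, seed=seed,
                         m_min=params.get("m_min", 5),
                         m_max=params.get("m_max", 30))
    elif selector == "cars":
        res = cars_select(X_tr, y_tr_code, seed=seed,
                          n_runs=params.get("n_runs", 100),
                          mc_fraction=params.get("mc_fraction", 0.8))
    else:
        raise ValueError(f"unknown selector {selector!r}")
    idx = res.selected_band_indices
    return X_tr[:, idx], X_te[:, idx], res


def run_grid(spectra_by_mode: dict, y, preprocessors: Sequence[str],
             selectors: Sequence[str], classifiers: Sequence[ClassifierSpec],
             seed: int = 0, train_fraction: float = 0.7143,
             selector_params: Optional[dict] = None,
             split: Optional[tuple] = None):
    """Full Cartesian sweep over modes × preprocessors × selectors × classifiers.

    ``spectra_by_mode`` maps a mode label to a :class:`SpectraMatrix` whose
    rows align with the label vector ``y`` (grade strings).  One stratified
    split (shared across modes) is drawn unless ``split`` is given.  Failed
    cells are recorded with their error and the sweep continues.

    Returns ``(results, best_by_mode)`` where ``best_by_mode`` maps the mode
    label to its winning :class:`GridResult`.
    """
    if not (spectra_by_mode and preprocessors and selectors and classifiers):
        raise ValueError("need at least one mode, preprocessor, selector "
                         "and classifier")
    y = np.asarray(y)
    if split is None:
        split = stratified_split(y, train_fraction, seed)
    tr_idx, te_idx = split
    y_tr, y_te = y[tr_idx], y[te_idx]
    y_tr_code = np.array([grade_code(g) for g in y_tr], dtype=float)

    results: list[GridResult] = []
    for mode_label, matrix in spectra_by_mode.items():
        X_tr_raw = SpectraMatrix(matrix.X[tr_idx], matrix.wavelengths_nm)
        X_te_raw = SpectraMatrix(matrix.X[te_idx], matrix.wavelengths_nm)
        for pre_name in preprocessors:
            try:
                pre = Preprocessor(method=pre_name)
                Xp_tr = pre.fit_transform(X_tr_raw).X
                Xp_te = pre.transform(X_te_raw).X
            except ValueError as exc:
                for sel_name in selectors:
                    for spec in classifiers:
                        results.append(_failed_cell(
                            mode_label, pre_name, sel_name, spec.kind,
                            f"preprocess: {exc}"))
                continue
            for sel_name in selectors:
                try:
                    F_tr, F_te, sel_res = _select_features(
                        sel_name, Xp_tr, Xp_te, y_tr_code, seed,
                        (selector_params or {}).get(sel_name))
                except ValueError as exc:
                    for spec in classifiers:
                        results.append(_failed_cell(
                            mode_label, pre_name, sel_name, spec.kind,
                            f"select: {exc}"))
                    continue
                for spec in classifiers:
                    try:
                        cell = train_and_eval(spec, F_tr, y_tr, F_te, y_te)
                        cell.mode = mode_label
                        cell.preprocessor = pre_name
                        cell.selector = sel_name
                        cell.selection = sel_res
                        results.append(cell)
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        results.append(_failed_cell(
                            mode_label, pre_name, sel_name, spec.kind,
                            f"classify: {exc}"))

    best_by_mode = {}
    for mode_label in spectra_by_mode:
        cells = [r for r in results if r.mode == mode_label and r.ok]
        if cells:
            best_by_mode[mode_label] = min(
                cells, key=lambda r: (-r.test_accuracy, -r.train_accuracy,
                                      r.pipeline_id))
    return results, best_by_mode


def _failed_cell(mode, pre, sel, clf, message) -> GridResult:
    logger.warning("grid cell %s/%s-%s-%s failed: %s",
                   mode, pre, sel, clf, message)
    return GridResult(mode=mode, preprocessor=pre, selector=sel,
                      classifier=clf, train_accuracy=float("nan"),
                      test_accuracy=float("nan"),
                      confusion=np.zeros((len(GRADES), len(GRADES)), dtype=int),
                      n_train=0, n_test=0, error=str(message))


def results_table(results: Sequence[GridResult]):
    """Grid results as a tidy DataFrame (accuracies in percent, 2 decimals)."""
    import pandas as pd

    rows = [{
        "mode": r.mode, "preprocessor": r.preprocessor,
        "selector": r.selector, "classifier": r.classifier,
        "train_accuracy_pct": round(100.0 * r.train_accuracy, 2),
        "test_accuracy_pct": round(100.0 * r.test_accuracy, 2),
        "n_train": r.n_train, "n_test": r.n_test,
        "error": r.error or "",
    } for r in results]
    return pd.DataFrame(rows)
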