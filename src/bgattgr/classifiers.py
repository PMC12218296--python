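"""Dimensionality reduction and the classifier bench.

PCA keeps the smallest number of leading components whose cumulative
explained variance reaches a threshold (default 95%); the transform is
fitted on training rows only and applied unchanged to test rows.  The
final model is an extremely-randomized-trees (ET) classifier; eleven
conventional baselines (MLP, ADA, RF, SVM, XGB, LGBM, DT, KNN, LDA, PLS,
LR) are tuned the same way — grid search by stratified 10-fold
cross-validation with AUPR (average precision) as the selection metric —
so comparisons are paired on identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "PcaTransform",
    "VariancePCA",
    "fit_pca",
    "apply_pca",
    "ClassifierSpec",
    "CLASSIFIER_NAMES",
    "DEFAULT_GRIDS",
    "make_classifier",
    "train_classifier",
    "predict_scores",
    "PLSDAClassifier",
]


# ---------------------------------------------------------------------------
# PCA at an explained-variance threshold

@dataclass
class PcaTransform:
    """A fitted, truncated PCA: training mean, components and variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # (k, width)
    explained_variance_ratio: np.ndarray
    k: int


def fit_pca(train_embeddings: np.ndarray, variance_threshold: float = 0.95) -> PcaTransform:
    """Fit PCA on training rows and truncate at the variance threshold.

    ``k`` is the smallest component count whose cumulative explained
    variance ratio reaches ``variance_threshold``; a threshold of 1.0 keeps
    every available component (min(n - 1, width)).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(f"variance_threshold must lie in (0, 1], got {variance_threshold}")
    X = np.asarray(train_embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit PCA")
    full = PCA(svd_solver="full").fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    if variance_threshold >= 1.0:
        k = len(cum)
    else:
        k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        k = min(k, len(cum))
    return PcaTransform(
        mean=full.mean_,
        components=full.components_[:k],
        explained_variance_ratio=full.explained_variance_ratio_[:k],
        k=k,
    )


def apply_pca(t: PcaTransform, embeddings: np.ndarray) -> np.ndarray:
    """Project rows with a training-fitted transform: ``(X - mean) @ components^T``."""
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[1] != t.mean.shape[0]:
        raise ValueError(
            f"embedding width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"the fitted width {t.mean.shape[0]}"
        )
    return (X - t.mean) @ t.components.T


class VariancePCA(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`fit_pca` / :func:`apply_pca`."""

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        self.transform_ = fit_pca(X, self.variance_threshold)
        self.n_components_ = self.transform_.k
        self.explained_variance_ratio_ = self.transform_.explained_variance_ratio
        return self

    def transform(self, X):
        check_is_fitted(self, "transform_")
        return apply_pca(self.transform_, X)


# ---------------------------------------------------------------------------
# The classifier bench

class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial-least-squares discriminant analysis.

    PLS regression on {0, 1} targets; the continuous response is clipped to
    [0, 1] as a score and thresholded at 0.5.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PLS-DA handles binary targets only")
        y01 = (y == self.classes_[1]).astype(float)
        n_comp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=n_comp).fit(X, y01)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pls_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        raw = np.clip(self.pls_.predict(X).ravel(), 0.0, 1.0)
        return np.column_stack([1 - raw, raw])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


CLASSIFIER_NAMES = ("ET", "MLP", "ADA", "RF", "SVM", "XGB", "LGBM", "DT", "KNN", "LDA", "PLS", "LR")

#: Declared default hyperparameter grids, fully overridable per spec of a run.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ET": {"n_estimators": [100, 250, 500]},
    "RF": {"n_estimators": [100, 250, 500]},
    "SVM": {"C": [0.1, 1, 10], "gamma": ["scale", 0.01]},
    "KNN": {"n_neighbors": [3, 5, 7]},
    "MLP": {"hidden_layer_sizes": [(64,), (128,)], "alpha": [1e-4, 1e-3]},
    "ADA": {"n_estimators": [50, 100, 250]},
    "XGB": {"n_estimators": [100, 250], "max_depth": [3, 6]},
    "LGBM": {"n_estimators": [100, 250], "num_leaves": [15, 31]},
    "DT": {"max_depth": [None, 5, 10]},
    "LDA": {},
    "PLS": {"n_components": [2, 5, 10]},
    "LR": {"C": [0.1, 1, 10]},
}


@dataclass
class ClassifierSpec:
    """One entry of the bench: name, its grid and the shared seed."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0
    chosen_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; supported: {CLASSIFIER_NAMES}"
            )
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.name].items()}


def make_classifier(name: str, seed: int = 0) -> BaseEstimator:
    """Instantiate a bench classifier by its short name."""
    if name == "ET":
        return ExtraTreesClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "MLP":
        return MLPClassifier(random_state=seed, max_iter=500)
    if name == "ADA":
        return AdaBoostClassifier(random_state=seed)
    if name == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, eval_metric="logloss")
    if name == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "PLS":
        return PLSDAClassifier()
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; supported: {CLASSIFIER_NAMES}")


def train_classifier(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 10,
    scoring: str = "average_precision",
) -> BaseEstimator:
    """Grid-search a bench classifier and refit it on all rows.

    Stratified ``cv_folds``-fold CV with a shared fold seed, selection by
    AUPR (average precision) by default.  A single-point grid skips the
    search and fits directly.
    """
    X, y = check_X_y(np.asarray(X, dtype=float), y)
    if len(np.unique(y)) != 2:
        raise ValueError("two classes required")
    base = make_classifier(spec.name, seed=spec.seed)
    n_candidates = len(list(ParameterGrid(spec.grid))) if spec.grid else 1
    if n_candidates <= 1:
        params = {k: v[0] for k, v in spec.grid.items()}
        model = clone(base).set_params(**params)
        model.fit(X, y)
        spec.chosen_params = params
        return model
    folds = min(cv_folds, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    search = GridSearchCV(
        base,
        spec.grid,
        scoring=scoring,
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed),
        refit=True,
        n_jobs=1,
    )
    search.fit(X, y)
    spec.chosen_params = search.best_params_
    return search.best_estimator_


def predict_scores(model: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class (``classes_[1]``) per row."""
    check_is_fitted(model)
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0)
    scores = model.predict_proba(X)[:, 1]
    return np.clip(scores, 0.0, 1.0)
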