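"""The end-to-end estimator: balance, embed, reduce, classify.

``BGATTGRPipeline`` chains the proportional SMOTE+RUS balancer (training
rows only), the BiGRU self-attention embedder, variance-threshold PCA and
an extremely-randomized-trees classifier into one sklearn-style binary
classifier.  Each stage can be switched off, which is what the ablation
experiments do:

* ``use_aug=False``  — train on the original, imbalanced rows;
* ``use_bgatt=False`` — the fused fingerprint vector goes to the final
  classifier directly (PCA is applied to embeddings only, so it is skipped
  too unless ``use_pca`` forces it).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .augmentation import build_balanced
from .classifiers import VariancePCA, make_classifier
from .network import BGATTClassifier

__all__ = ["BGATTGRPipeline"]


class BGATTGRPipeline(BaseEstimator, ClassifierMixin):
    """Balance -> BGATT embedding -> PCA -> classifier, as one estimator.

    Parameters
    ----------
    use_aug : bool
        Apply the proportional SMOTE+RUS balancer to the training rows.
    use_bgatt : bool
        Train the BiGRU self-attention embedder and classify its embeddings;
        when off, the classifier sees the raw fused features.
    use_pca : bool or "auto"
        "auto" applies the variance-threshold PCA exactly when the
        embedder is on (the reduction targets the embedding space).
    p : float in [0, 1]
        SMOTE proportion of the balancer.
    k : int
        SMOTE neighbour count.
    variance_threshold : float
        Explained-variance fraction retained by PCA.
    classifier : str
        Final-classifier short name (default "ET", extremely randomized
        trees) instantiated with library defaults; pass a fitted-parameter
        dict via ``classifier_params``.
    view_offsets : mapping, optional
        Descriptor-view column ranges forwarded to the embedder.
    bgatt_params : mapping, optional
        Overrides for the :class:`~bgattgr.network.BGATTClassifier`
        constructor (d_model, d_h, epochs, ...).
    random_state : int
        Master seed; stage seeds are derived from it.
    """

    def __init__(
        self,
        use_aug: bool = True,
        use_bgatt: bool = True,
        use_pca: bool | str = "auto",
        p: float = 0.75,
        k: int = 5,
        variance_threshold: float = 0.95,
        classifier: str = "ET",
        classifier_params: Mapping | None = None,
        view_offsets: Mapping | None = None,
        bgatt_params: Mapping | None = None,
        random_state: int = 0,
    ):
        self.use_aug = use_aug
        self.use_bgatt = use_bgatt
        self.use_pca = use_pca
        self.p = p
        self.k = k
        self.variance_threshold = variance_threshold
        self.classifier = classifier
        self.classifier_params = classifier_params
        self.view_offsets = view_offsets
        self.bgatt_params = bgatt_params
        self.random_state = random_state

    def _apply_pca(self) -> bool:
        if self.use_pca == "auto":
            return self.use_bgatt
        return bool(self.use_pca)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BGATTGRPipeline":
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31, size=3)

        if self.use_aug:
            balanced = build_balanced(X, y, p=self.p, k=self.k, seed=int(seeds[0]))
            X_train, y_train = balanced.features, balanced.labels
            self.balanced_ = balanced
        else:
            X_train, y_train = X, y
            self.balanced_ = None

        if self.use_bgatt:
            params = dict(self.bgatt_params or {})
            params.setdefault("random_state", int(seeds[1]))
            self.embedder_ = BGATTClassifier(view_offsets=self.view_offsets, **params)
            self.embedder_.fit(X_train, y_train)
            Z = self.embedder_.transform(X_train)
        else:
            self.embedder_ = None
            Z = X_train

        if self._apply_pca():
            self.pca_ = VariancePCA(self.variance_threshold).fit(Z)
            Z = self.pca_.transform(Z)
        else:
            self.pca_ = None

        clf = make_classifier(self.classifier, seed=int(seeds[2]))
        if self.classifier_params:
            clf.set_params(**dict(self.classifier_params))
        self.classifier_ = clf.fit(Z, y_train)
        return self

    def _featurize(self, X: np.ndarray) -> np.ndarray:
        Z = self.embedder_.transform(X) if self.embedder_ is not None else X
        if self.pca_ is not None:
            Z = self.pca_.transform(Z)
        return Z

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty((0, 2))
        return self.classifier_.predict_proba(self._featurize(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classifier_.classes_[np.argmax(proba, axis=1)]

    def score_positive(self, X: np.ndarray, positive_class) -> np.ndarray:
        """Probability of ``positive_class`` per row."""
        proba = self.predict_proba(X)
        col = int(np.where(self.classifier_.classes_ == positive_class)[0][0])
        return proba[:, col]
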