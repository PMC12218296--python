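"""Proportional SMOTE + random undersampling for 1:1 class balancing.

The balancer interpolates the class sizes between the minority and majority
counts: at proportion ``p`` the per-class target is

    target = round(n_min + p * (n_maj - n_min))

SMOTE synthesizes ``target - n_min`` minority rows (linear interpolation
toward one of the k nearest minority neighbours), and the majority class is
uniformly undersampled without replacement down to ``target``, so every
output is exactly 1:1 balanced.  At p=0 this is pure undersampling
(2*n_min rows); at p=1 pure oversampling (2*n_maj rows).

Synthetic fingerprint values are left continuous in [0, 1]; they are not
re-binarized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "BalancedDataset",
    "smote_oversample",
    "build_balanced",
    "foldwise_balance",
    "ProportionalSMOTERUS",
]


@dataclass
class BalancedDataset:
    """A 1:1 balanced training set with provenance of each row."""

    features: np.ndarray
    labels: np.ndarray
    proportion_p: float
    synthetic_mask: np.ndarray  # True where the row was SMOTE-generated
    seed: int

    def __post_init__(self) -> None:
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) == 2 and counts[0] != counts[1]:
            raise ValueError(f"balanced dataset has unequal class counts {dict(zip(classes, counts))}")

    @property
    def n_synthetic(self) -> int:
        return int(self.synthetic_mask.sum())


def smote_oversample(
    minority: np.ndarray, n_new: int, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Generate ``n_new`` synthetic minority rows by SMOTE interpolation.

    Each synthetic point is ``x_i + lam * (x_nn - x_i)`` for a uniformly
    drawn parent ``x_i``, one of its ``k`` nearest minority neighbours
    ``x_nn`` (Euclidean, excluding itself) and ``lam ~ Uniform(0, 1)``.
    Deterministic under ``seed``.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2:
        raise ValueError("minority must be a 2-D matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    if minority.shape[0] < k + 1:
        raise ValueError(
            f"need at least k+1={k + 1} minority rows for k={k} neighbours, "
            f"got {minority.shape[0]}; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    # first neighbour is the point itself; keep the k real neighbours
    neighbour_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]

    parents = rng.integers(0, minority.shape[0], size=n_new)
    choices = rng.integers(0, k, size=n_new)
    lams = rng.uniform(0.0, 1.0, size=n_new)
    x_i = minority[parents]
    x_nn = minority[neighbour_idx[parents, choices]]
    return x_i + lams[:, None] * (x_nn - x_i)


def balanced_target(n_min: int, n_maj: int, p: float) -> int:
    """Per-class size at SMOTE proportion ``p``: round(n_min + p*(n_maj-n_min))."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion p must lie in [0, 1], got {p}")
    return int(round(n_min + p * (n_maj - n_min)))


def build_balanced(
    features: np.ndarray,
    labels: np.ndarray,
    p: float,
    k: int = 5,
    seed: int = 0,
) -> BalancedDataset:
    """Build the 1:1 balanced dataset at SMOTE proportion ``p``.

    The minority class is identified by count; SMOTE raises it to the target
    size and the majority class is uniformly undersampled to the same size.
    The output row order is shuffled under ``seed``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    minority_cls = classes[np.argmin(counts)]
    majority_cls = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority_cls, majority_cls = classes[0], classes[1]
    n_min, n_maj = counts.min(), counts.max()
    target = balanced_target(int(n_min), int(n_maj), p)

    rng = np.random.default_rng(seed)
    min_rows = features[labels == minority_cls]
    maj_rows = features[labels == majority_cls]

    n_new = target - len(min_rows)
    synth = smote_oversample(min_rows, n_new, k=k, seed=int(rng.integers(2**31)))
    keep_maj = rng.choice(len(maj_rows), size=target, replace=False)

    X = np.concatenate([min_rows, synth, maj_rows[keep_maj]], axis=0)
    y = np.concatenate(
        [
            np.full(len(min_rows) + n_new, minority_cls),
            np.full(target, majority_cls),
        ]
    )
    mask = np.zeros(len(X), dtype=bool)
    mask[len(min_rows) : len(min_rows) + n_new] = True

    order = rng.permutation(len(X))
    return BalancedDataset(
        features=X[order],
        labels=y[order],
        proportion_p=float(p),
        synthetic_mask=mask[order],
        seed=seed,
    )


def foldwise_balance(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int,
    p: float,
    k: int = 5,
    seed: int = 0,
) -> list[tuple[BalancedDataset, np.ndarray, np.ndarray]]:
    """Leakage-safe cross-validation plumbing.

    Splits stratified folds, balances only each training portion and leaves
    the validation portion untouched; returns ``(balanced_train,
    X_validation, y_validation)`` per fold.  Synthetic rows therefore never
    occur in any validation fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for i, (tr, va) in enumerate(skf.split(features, labels)):
        if len(np.unique(labels[va])) < 2 or len(np.unique(labels[tr])) < 2:
            raise ValueError(f"fold {i} contains a single class; use fewer folds")
        balanced = build_balanced(features[tr], labels[tr], p=p, k=k, seed=seed + i)
        out.append((balanced, features[va], labels[va]))
    return out


class ProportionalSMOTERUS:
    """Estimator-style wrapper around :func:`build_balanced`.

    Follows the imbalanced-learn ``fit_resample`` convention so it can slot
    into resampling-aware pipelines.

    Parameters
    ----------
    p : float in [0, 1]
        SMOTE proportion; interpolates the per-class size between the
        minority (p=0) and the majority (p=1) count.
    k : int
        Number of nearest minority neighbours used by SMOTE.
    random_state : int
        Seed for neighbour choice, interpolation and undersampling.
    """

    def __init__(self, p: float = 0.75, k: int = 5, random_state: int = 0):
        self.p = p
        self.k = k
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"p": self.p, "k": self.k, "random_state": self.random_state}

    def set_params(self, **params) -> "ProportionalSMOTERUS":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit_resample(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        balanced = build_balanced(X, y, p=self.p, k=self.k, seed=self.random_state)
        self.dataset_ = balanced
        self.synthetic_mask_ = balanced.synthetic_mask
        return balanced.features, balanced.labels
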