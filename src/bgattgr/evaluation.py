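"""Performance metrics, cross-validation, ablations and plots.

Threshold metrics follow the confusion matrix with an explicitly declared
positive class (by default the minority class — for the glucocorticoid-
receptor dataset, the inactives):

    SN = TP / (TP + FN)            (sensitivity / recall)
    SP = TN / (TN + FP)            (specificity)
    BACC = (SN + SP) / 2           (balanced accuracy)
    F1 = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention that a ratio with a zero denominator (and MCC with any
zero factor) is 0.  Ranking metrics: AUC by the trapezoidal rule over the
ROC curve, AUPR by step-wise precision-recall summation (average
precision).

``recover_cm_from_rates`` inverts printed (SN, SP) pairs back to the
integer confusion matrix by exhaustive search — the tool used to check
published result tables cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import (
    auc as _trapezoid_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .augmentation import build_balanced
from .pipeline import BGATTGRPipeline

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics_from_cm",
    "recover_cm_from_rates",
    "roc_pr_curves",
    "score_report",
    "run_cv",
    "run_ablation",
    "ABLATION_STRATEGIES",
    "tsne_plot",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: object = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    sn: float
    sp: float
    bacc: float
    mcc: float
    f1: float
    auc: float | None = None
    aupr: float | None = None
    cm: ConfusionMatrix | None = None
    mode: str = "independent"
    positive_class: object = 1

    def to_dict(self) -> dict:
        out = {
            "sn": self.sn, "sp": self.sp, "bacc": self.bacc,
            "mcc": self.mcc, "f1": self.f1, "auc": self.auc, "aupr": self.aupr,
            "mode": self.mode, "positive_class": str(self.positive_class),
        }
        if self.cm is not None:
            out.update(tp=self.cm.tp, fn=self.cm.fn, tn=self.cm.tn, fp=self.cm.fp)
        return out


def confusion(labels: Sequence, predicted: Sequence, positive_class) -> ConfusionMatrix:
    """Standard confusion counts with a declared positive class."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predicted.shape}")
    if labels.size == 0:
        raise ValueError("empty label arrays")
    pos = labels == positive_class
    pred_pos = predicted == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        positive_class=positive_class,
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_cm(cm: ConfusionMatrix, mode: str = "independent") -> MetricsReport:
    """Threshold metrics from a confusion matrix (0-conventions for degenerate cells)."""
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den else 0.0
    return MetricsReport(
        sn=sn,
        sp=sp,
        bacc=(sn + sp) / 2.0,
        mcc=float(mcc),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        cm=cm,
        mode=mode,
        positive_class=cm.positive_class,
    )


def recover_cm_from_rates(
    sn: float,
    sp: float,
    n_pos: int,
    n_neg: int,
    decimals: int = 3,
) -> ConfusionMatrix | list[ConfusionMatrix]:
    """Invert printed (SN, SP) back to integer confusion-matrix cells.

    Exhaustively searches tp in [0, n_pos] and tn in [0, n_neg] for cells
    whose rates round to the given values at ``decimals`` places.  Returns
    the unique match, or the list of all matches when several fit; raises
    if none do (which flags a table inconsistency).
    """
    tps = [tp for tp in range(n_pos + 1) if round(tp / n_pos, decimals) == round(sn, decimals)]
    tns = [tn for tn in range(n_neg + 1) if round(tn / n_neg, decimals) == round(sp, decimals)]
    matches = [
        ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
        for tp in tps
        for tn in tns
    ]
    if not matches:
        raise ValueError(
            f"no integer confusion matrix with SN={sn}, SP={sp} on {n_pos}/{n_neg}: "
            "the printed rates are inconsistent with the class sizes"
        )
    return matches[0] if len(matches) == 1 else matches


def roc_pr_curves(scores: Sequence[float], labels: Sequence, positive_class):
    """AUC, AUPR and the curve point lists for one score vector.

    AUC is the trapezoidal area under the ROC curve over all score
    thresholds (ties grouped); AUPR is the step-wise precision-recall
    summation (average precision).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = (labels == positive_class).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute curves")
    fpr, tpr, _ = roc_curve(y, scores)
    precision, recall, _ = precision_recall_curve(y, scores)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    aupr_value = float(average_precision_score(y, scores))
    return auc_value, aupr_value, list(zip(fpr, tpr)), list(zip(recall, precision))


def score_report(
    y_true: Sequence,
    scores_pos: Sequence[float],
    positive_class,
    threshold: float = 0.5,
    mode: str = "independent",
) -> MetricsReport:
    """Full report (threshold + ranking metrics) from positive-class scores."""
    y_true = np.asarray(y_true)
    scores_pos = np.asarray(scores_pos, dtype=float)
    predicted = np.where(scores_pos >= threshold, positive_class, _other_class(y_true, positive_class))
    cm = confusion(y_true, predicted, positive_class)
    report = metrics_from_cm(cm, mode=mode)
    report.auc, report.aupr, _, _ = roc_pr_curves(scores_pos, y_true, positive_class)
    return report


def _other_class(y: np.ndarray, positive_class):
    classes = np.unique(y)
    others = [c for c in classes if c != positive_class]
    return others[0] if others else positive_class


def minority_class(y: Sequence):
    """The positive class used by default: the rarer label."""
    classes, counts = np.unique(np.asarray(y), return_counts=True)
    return classes[np.argmin(counts)]


def _mean_report(reports: list[MetricsReport], mode: str) -> MetricsReport:
    return MetricsReport(
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        bacc=float(np.mean([r.bacc for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
        aupr=float(np.mean([r.aupr for r in reports])),
        mode=mode,
        positive_class=reports[0].positive_class,
    )


def run_cv(
    pipeline: BGATTGRPipeline,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    positive_class=None,
    mode: str = "safe",
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold cross-validation of the full pipeline.

    ``mode="safe"`` (default) balances inside each training fold only, so
    no SMOTE row can leak into a validation fold.  ``mode="paper"``
    balances the whole set once and then cross-validates the balanced data
    (the protocol many published tables appear to use); reports name the
    mode.  Per-fold metrics are macro-averaged.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if mode not in ("safe", "paper"):
        raise ValueError(f"mode must be 'safe' or 'paper', got {mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if positive_class is None:
        positive_class = minority_class(y)

    if mode == "paper":
        balanced = build_balanced(X, y, p=pipeline.p, k=pipeline.k, seed=seed)
        X, y = balanced.features, balanced.labels
        pipeline = clone(pipeline).set_params(use_aug=False)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_reports = []
    for i, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[va])) < 2:
            raise ValueError(f"validation fold {i} contains a single class")
        model = clone(pipeline).set_params(random_state=seed + i)
        model.fit(X[tr], y[tr])
        scores = model.score_positive(X[va], positive_class)
        fold_reports.append(
            score_report(y[va], scores, positive_class, mode=f"cv_fold_{mode}")
        )
    return _mean_report(fold_reports, mode=f"cv_mean_{mode}"), fold_reports


ABLATION_STRATEGIES = {
    "-AUG-BGATT": dict(use_aug=False, use_bgatt=False),
    "+AUG-BGATT": dict(use_aug=True, use_bgatt=False),
    "-AUG+BGATT": dict(use_aug=False, use_bgatt=True),
    "+AUG+BGATT": dict(use_aug=True, use_bgatt=True),
}


def run_ablation(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    base_pipeline: BGATTGRPipeline | None = None,
    folds: int = 10,
    seed: int = 0,
    positive_class=None,
    include_cv: bool = True,
    cv_mode: str = "safe",
    strategies: Sequence[str] | None = None,
) -> dict[str, dict[str, MetricsReport]]:
    """The four-strategy ablation: toggle the balancer and the embedder.

    Each strategy trains on the training rows and is scored on the
    untouched independent test set; optionally also by ``run_cv`` on the
    training rows.  Returns ``{strategy: {"independent": report,
    "cv": report}}``.
    """
    if base_pipeline is None:
        base_pipeline = BGATTGRPipeline(random_state=seed)
    if positive_class is None:
        positive_class = minority_class(y_train)
    names = list(strategies) if strategies is not None else list(ABLATION_STRATEGIES)
    results: dict[str, dict[str, MetricsReport]] = {}
    for name in names:
        toggles = ABLATION_STRATEGIES[name]
        pipe = clone(base_pipeline).set_params(**toggles)
        out: dict[str, MetricsReport] = {}
        if include_cv:
            out["cv"], _ = run_cv(
                pipe, X_train, y_train, folds=folds, seed=seed,
                positive_class=positive_class, mode=cv_mode,
            )
        model = clone(pipe).set_params(random_state=seed)
        model.fit(X_train, y_train)
        scores = model.score_positive(X_test, positive_class)
        out["independent"] = score_report(y_test, scores, positive_class)
        results[name] = out
    return results


def tsne_plot(
    features: np.ndarray,
    labels: Sequence,
    perplexity: float = 30.0,
    seed: int = 0,
    path: str | Path | None = None,
    active_label=None,
):
    """2-D t-SNE map of a feature matrix, colored by activity class.

    Returns the ``n x 2`` coordinates; writes a scatter plot (active green,
    inactive red) when ``path`` is given.  Qualitative only.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than 3*perplexity={3 * perplexity:.0f} rows, got {X.shape[0]}"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, learning_rate="auto",
        init="pca", random_state=seed,
    ).fit_transform(X)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if active_label is None:
            classes, counts = np.unique(labels, return_counts=True)
            active_label = classes[np.argmax(counts)]
        fig, ax = plt.subplots(figsize=(5, 5))
        for cls, color in ((active_label, "tab:green"),):
            m = labels == cls
            ax.scatter(coords[m, 0], coords[m, 1], s=8, c=color, label=str(cls))
        m = labels != active_label
        ax.scatter(coords[m, 0], coords[m, 1], s=8, c="tab:red", label="other")
        ax.legend()
        ax.set_xlabel("t-SNE 1")
        ax.set_ylabel("t-SNE 2")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return coords
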