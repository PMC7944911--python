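"""Linear SVM genotype classifier with nested two-step grid search and LOOCV.

The regularization constant C is tuned per outer fold by a two-step grid
search: a coarse log2-spaced sweep scored by inner stratified-CV accuracy,
then a finer multiplicative grid centered on the coarse winner (ties break
toward smaller C).  Leave-one-out cross-validation holds each subject out
once; the held-out signed decision value is recorded, and one ROC is built
from the n pooled decision values.  AUC uses the all-pairs concordance
formula with ties counted 1/2.  Age can optionally be appended as a feature,
standardized with training-fold statistics only.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import LabelRatioFeatureTable

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "precision", "recall", "f1")

# libsvm can thrash for minutes at very large C on noisy data; such C values
# never win model selection there, so cap the solver to keep sweeps bounded
SVC_MAX_ITER = 100_000


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    svc = SVC(kernel="linear", C=C, max_iter=SVC_MAX_ITER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    return svc


def _default_coarse_grid() -> tuple[float, ...]:
    return tuple(float(2.0**e) for e in range(-15, 16, 2))


@dataclass
class SVMConfig:
    """Hyperparameter-search and evaluation settings for the linear SVM."""

    coarse_grid: tuple[float, ...] = field(default_factory=_default_coarse_grid)
    fine_steps: int = 9
    fine_span: float = 4.0  # fine grid spans [C/span, C*span] around the coarse winner
    inner_cv_folds: int = 5
    positive_class: str = "wildtype"
    include_age: bool = False
    seed: int = 0

    def validate(self) -> None:
        if any(c <= 0 for c in self.coarse_grid):
            raise ValueError("all C candidates must be positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if self.positive_class not in ("wildtype", "mutant"):
            raise ValueError("positive_class must be 'wildtype' or 'mutant'")
        if self.fine_steps < 1 or self.fine_span <= 1:
            raise ValueError("fine grid must have >= 1 step and span > 1")

    def fine_grid(self, center: float) -> tuple[float, ...]:
        mult = np.exp(np.linspace(-np.log(self.fine_span), np.log(self.fine_span), self.fine_steps))
        return tuple(sorted(float(center * m) for m in mult))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CVClassificationReport:
    """Pooled LOOCV predictions, confusion counts and the seven metrics."""

    subject_ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    decision_values: np.ndarray
    chosen_C: np.ndarray
    confusion: dict[str, int]
    metrics: dict[str, float]
    positive_class: str
    config_hash: str
    warnings: tuple[str, ...] = ()

    def to_json(self) -> str:
        """Canonical serialization (sorted keys, no timestamps): two runs
        with identical config and seed produce byte-identical output."""
        payload = {
            "subject_ids": list(self.subject_ids),
            "y_true": [str(v) for v in self.y_true],
            "y_pred": [str(v) for v in self.y_pred],
            "decision_values": [float(v) for v in self.decision_values],
            "chosen_C": [float(v) for v in self.chosen_C],
            "confusion": self.confusion,
            "metrics": {k: (None if np.isnan(v) else float(v)) for k, v in self.metrics.items()},
            "positive_class": self.positive_class,
            "config_hash": self.config_hash,
            "warnings": list(self.warnings),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, folds: list) -> float:
    correct = 0
    for train_idx, test_idx in folds:
        svc = _fit_svc(X[train_idx], y[train_idx], C)
        correct += int(np.sum(svc.predict(X[test_idx]) == y[test_idx]))
    return correct / len(y)


def _inner_folds(y: np.ndarray, n_folds: int, seed: int) -> list:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class; cannot tune C")
    k = int(min(n_folds, counts.min()))
    if k < 2:
        raise ValueError("need at least 2 subjects per class for inner CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return list(skf.split(np.zeros(len(y)), y))


def two_step_grid_search(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    config: SVMConfig,
) -> float:
    """Best C by coarse-then-fine inner-CV accuracy; ties toward smaller C."""
    config.validate()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    folds = _inner_folds(y, config.inner_cv_folds, config.seed)

    def best_of(grid: Sequence[float]) -> float:
        grid = sorted(grid)
        scores = [_cv_accuracy(X, y, C, folds) for C in grid]
        return grid[int(np.argmax(scores))]  # first max = smallest C on ties

    coarse_best = best_of(config.coarse_grid)
    return best_of(config.fine_grid(coarse_best))


def _design_matrix(table: LabelRatioFeatureTable) -> tuple[np.ndarray, np.ndarray]:
    X = table.log_ratios.T.copy()
    y = np.asarray(table.genotype)
    return X, y


def _append_age(X_train, X_test, age_train, age_test):
    mu = age_train.mean()
    sd = age_train.std()
    sd = sd if sd > 0 else 1.0
    return (
        np.column_stack([X_train, (age_train - mu) / sd]),
        np.column_stack([X_test, (age_test - mu) / sd]),
    )


def loocv_classify(table: LabelRatioFeatureTable, config: SVMConfig) -> CVClassificationReport:
    """Leave-one-out evaluation with per-fold grid search.

    Each held-out subject is scored by a model whose hyperparameter search
    and (optional) age standardization see only the remaining subjects.
    Metrics pool all n held-out decision values.
    """
    config.validate()
    X, y = _design_matrix(table)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("LOOCV requires at least 2 subjects per class")

    warnings: list[str] = []
    if np.all(np.ptp(X, axis=0) == 0):
        warnings.append("degenerate feature table: all feature rows constant")

    decisions = np.empty(n)
    preds = np.empty(n, dtype=y.dtype)
    chosen = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, X_te = X[mask], X[~mask]
        y_tr = y[mask]
        if config.include_age:
            X_tr, X_te = _append_age(X_tr, X_te, table.age[mask], table.age[~mask])
        C = two_step_grid_search(X_tr, y_tr, config)
        svc = _fit_svc(X_tr, y_tr, C)
        dv = float(svc.decision_function(X_te)[0])
        # decision_function is positive toward classes_[1]; orient toward
        # the configured positive class
        if svc.classes_[1] != config.positive_class:
            dv = -dv
        decisions[i] = dv
        preds[i] = svc.predict(X_te)[0]
        chosen[i] = C

    metrics, confusion = compute_metrics(
        decisions, preds, y, config.positive_class, return_confusion=True
    )
    return CVClassificationReport(
        subject_ids=tuple(table.subject_ids),
        y_true=y,
        y_pred=preds,
        decision_values=decisions,
        chosen_C=chosen,
        confusion=confusion,
        metrics=metrics,
        positive_class=config.positive_class,
        config_hash=config.hash(),
        warnings=tuple(warnings),
    )


def pairwise_auc(decision_values: np.ndarray, truth: np.ndarray, positive_class: str) -> float:
    """AUC as the all-pairs concordance fraction, ties counted 1/2."""
    dv = np.asarray(decision_values, dtype=float)
    pos = dv[np.asarray(truth) == positive_class]
    neg = dv[np.asarray(truth) != positive_class]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(
    decision_values: np.ndarray,
    predictions: np.ndarray,
    truth: np.ndarray,
    positive_class: str,
    return_confusion: bool = False,
):
    """The seven summary metrics from pooled decisions and predictions.

    Zero-denominator metrics are reported as NaN rather than silently 0.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if len(truth) != len(predictions) or len(truth) != len(decision_values):
        raise ValueError("decision_values, predictions, truth must share length")
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present in truth")

    pos_true = truth == positive_class
    pos_pred = predictions == positive_class
    tp = int(np.sum(pos_true & pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    fn = int(np.sum(pos_true & ~pos_pred))
    tn = int(np.sum(~pos_true & ~pos_pred))

    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    recall = sensitivity
    f1 = (
        _safe_div(2 * precision * recall, precision + recall)
        if np.isfinite(precision) and np.isfinite(recall)
        else float("nan")
    )
    metrics = {
        "auc": pairwise_auc(decision_values, truth, positive_class),
        "accuracy": (tp + tn) / len(truth),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
    if return_confusion:
        return metrics, {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    return metrics
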