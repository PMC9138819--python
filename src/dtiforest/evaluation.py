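"""Evaluation: confusion metrics, ROC/AUC, stratified cross-validation, grid
search over classifier parameters, and ranking of candidate interactions.

Metrics follow the usual binary definitions with class 1 positive:

    Accu = (TP+TN)/(TP+TN+FP+FN)     Sen = TP/(TP+FN)     Prec = TP/(TP+FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

Any metric with a zero denominator is reported as 0 so cross-validation
aggregation stays total. Cross-validation summaries report the mean and the
population standard deviation per metric, formatted in percent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataset import InteractionNetwork, Pair, assemble_matrix
from .fwrf import FeatureWeightedRotationForest


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class FoldMetrics:
    accuracy: float
    sensitivity: float
    precision: float
    mcc: float
    auc: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "mcc": self.mcc,
            "auc": self.auc,
        }


METRIC_NAMES = ("accuracy", "sensitivity", "precision", "mcc", "auc")


def _check_binary(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return y.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with class 1 as the positive class."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics_from_counts(counts: ConfusionCounts, auc_value: float = 0.0) -> FoldMetrics:
    """Accuracy, sensitivity, precision and MCC from confusion counts.

    Degenerate denominators yield 0 for the affected metric (documented
    policy); the AUC slot is filled by the caller when scores exist.
    """
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tn + fn) * float(tp + fn) * float(tn + fp)
    )
    return FoldMetrics(
        accuracy=_safe_div(tp + tn, counts.total),
        sensitivity=_safe_div(tp, tp + fn),
        precision=_safe_div(tp, tp + fp),
        mcc=_safe_div(tp * tn - fp * fn, mcc_den),
        auc=auc_value,
        counts=counts,
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points by descending-threshold sweep plus the trapezoid AUC.

    The AUC equals the probability a random positive outscores a random
    negative, ties counted one half. Returns (points, auc) where points is
    an (n, 2) array of (FPR, TPR).
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if y_true.size != scores.size:
        raise ValueError("y_true and scores length mismatch")
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(y_true, scores)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class CVReport:
    """Per-fold metrics with mean / population-std summaries.

    ``formatted`` renders each metric as the conventional percent string,
    e.g. ``"91.68 ± 0.84"``.
    """

    per_fold: tuple[FoldMetrics, ...]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(m, metric) for m in self.per_fold]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(m, metric) for m in self.per_fold]))

    @property
    def formatted(self) -> dict[str, str]:
        return {
            name: f"{100 * self.mean(name):.2f} ± {100 * self.std(name):.2f}"
            for name in METRIC_NAMES
        }

    def as_dict(self) -> dict:
        return {
            "params": self.params,
            "seed": self.seed,
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": {name: self.mean(name) for name in METRIC_NAMES},
            "std": {name: self.std(name) for name in METRIC_NAMES},
            "formatted": self.formatted,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.as_dict(), **kwargs)

    def __str__(self) -> str:
        lines = ["fold  " + "  ".join(f"{n:>11}" for n in METRIC_NAMES)]
        for i, m in enumerate(self.per_fold, start=1):
            lines.append(
                f"{i:>4}  " + "  ".join(f"{100 * getattr(m, n):11.2f}" for n in METRIC_NAMES)
            )
        lines.append(
            "mean  " + "  ".join(f"{self.formatted[n]:>11}" for n in METRIC_NAMES)
        )
        return "\n".join(lines)


def _evaluate_fold(model: FeatureWeightedRotationForest, X_test: np.ndarray,
                   y_test: np.ndarray) -> FoldMetrics:
    y_pred = model.predict(X_test)
    scores = model.predict_confidence(X_test)[:, 1]
    counts = confusion(y_test, y_pred)
    _, auc_value = roc_auc(y_test, scores)
    return metrics_from_counts(counts, auc_value=auc_value)


def cross_validate(X: np.ndarray, y: np.ndarray, folds: int = 5,
                   params: dict | None = None, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of the rotation forest.

    Folds are stratified and shuffled under the seed; each fold trains a
    fresh model (its seed derived from the fold index) and is scored on the
    held-out split.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y, "y")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > min(int((y == 0).sum()), int((y == 1).sum())):
        raise ValueError("more folds than members of the rarer class")
    params = dict(params or {})
    params.pop("seed", None)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for fold_idx, (train, test) in enumerate(splitter.split(X, y)):
        model = FeatureWeightedRotationForest(seed=seed * 1000 + fold_idx, **params)
        model.fit(X[train], y[train])
        per_fold.append(_evaluate_fold(model, X[test], y[test]))
    return CVReport(per_fold=tuple(per_fold), params=params, seed=seed)


def grid_search(X: np.ndarray, y: np.ndarray, grid: list[dict],
                folds: int = 5, seed: int = 0,
                datasets_by_lag: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
                ) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search ranked by mean cross-validated accuracy.

    Each grid entry is a dict of ``FeatureWeightedRotationForest`` parameters,
    optionally with a ``lag_max`` key when ``datasets_by_lag`` maps each Λ to
    its own re-featurized (X, y). Ties keep the first entry in grid order.
    Returns (best params, full results table).
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    rows = []
    best: dict | None = None
    best_acc = -np.inf
    for entry in grid:
        entry = dict(entry)
        lag = entry.pop("lag_max", None)
        if lag is not None:
            if datasets_by_lag is None or lag not in datasets_by_lag:
                raise ValueError(f"no dataset provided for lag_max={lag}")
            Xe, ye = datasets_by_lag[lag]
        else:
            Xe, ye = X, y
        report = cross_validate(Xe, ye, folds=folds, params=entry, seed=seed)
        row = {**entry}
        if lag is not None:
            row["lag_max"] = lag
        for name in METRIC_NAMES:
            row[f"mean_{name}"] = report.mean(name)
            row[f"std_{name}"] = report.std(name)
        rows.append(row)
        if report.mean("accuracy") > best_acc:
            best_acc = report.mean("accuracy")
            best = dict(entry) if lag is None else {**entry, "lag_max": lag}
    return best, pd.DataFrame(rows)


def rank_candidates(model: FeatureWeightedRotationForest, net: InteractionNetwork,
                    fingerprints: dict, descriptors: dict, top_k: int = 10,
                    ) -> list[tuple[str, str, float]]:
    """Score every pair outside the known positives and return the top_k.

    Scores are class-1 confidences; the list is sorted by descending score
    with (drug_id, target_id) lexicographic tie-break.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    unknown = net.unknown_pairs()
    if not unknown:
        return []
    drug_vecs = {d: fingerprints[d].bits.astype(float) for d in net.drugs}
    target_vecs = {t: descriptors[t].vector for t in net.targets}
    X = np.array([np.concatenate([drug_vecs[d], target_vecs[t]]) for d, t in unknown])
    scores = model.predict_confidence(X)[:, 1]
    ranked = sorted(
        zip(unknown, scores), key=lambda item: (-item[1], item[0][0], item[0][1])
    )
    return [(d, t, float(s)) for (d, t), s in ranked[:top_k]]
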