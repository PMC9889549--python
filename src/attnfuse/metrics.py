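"""Multiclass evaluation: sensitivity, accuracy, specificity and AUROC,
aggregated as mean +/- std over cross-validation folds.

Sensitivity, specificity and AUROC use macro one-vs-rest averaging (the only
convention that yields all four metrics for K >= 3).  AUROC is computed by
the rank-sum (Mann-Whitney) formulation with midrank tie handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["MetricsReport", "confusion_matrix", "multiclass_metrics",
           "auroc_ovr", "aggregate_folds"]

METRIC_NAMES = ("sensitivity", "accuracy", "specificity", "auroc")


@dataclass
class MetricsReport:
    """Per-metric (mean, std) pairs over folds."""

    sensitivity: tuple[float, float]
    accuracy: tuple[float, float]
    specificity: tuple[float, float]
    auroc: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = {f.name: {"mean": getattr(self, f.name)[0], "std": getattr(self, f.name)[1]}
                for f in fields(self)}
        return pd.DataFrame(rows).T

    def __str__(self):
        parts = [f"{f.name}={getattr(self, f.name)[0]:.3f} ± {getattr(self, f.name)[1]:.3f}"
                 for f in fields(self)]
        return "  ".join(parts)


def confusion_matrix(labels, predicted, n_classes: int) -> np.ndarray:
    """K x K count matrix; entry (true, pred)."""
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if labels.shape != predicted.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {predicted.shape}")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes
                        or predicted.min() < 0 or predicted.max() >= n_classes):
        raise ValueError("labels/predictions out of range")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (labels, predicted), 1)
    return cm


def _binary_auroc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUROC with midranks: P(score_pos > score_neg) + 0.5 ties."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(score)  # midranks
    rank_sum = ranks[y == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auroc_ovr(labels, scores) -> float:
    """Macro one-vs-rest AUROC; scores is (n, K) per-class probabilities."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    aucs = []
    for k in range(scores.shape[1]):
        auc = _binary_auroc((labels == k).astype(int), scores[:, k])
        if np.isnan(auc):
            warnings.warn(f"class {k} absent from labels; excluded from macro AUROC")
            continue
        aucs.append(auc)
    return float(np.mean(aucs))


def multiclass_metrics(confusion: np.ndarray, scores=None, labels=None) -> dict:
    """Metrics from a confusion matrix (+ per-class scores for AUROC).

    sensitivity = macro one-vs-rest recall; specificity = macro one-vs-rest
    true-negative rate; accuracy = trace / n.  Classes absent from the
    labels are excluded from the macro averages with a warning.
    """
    cm = np.asarray(confusion)
    n = cm.sum()
    k = cm.shape[0]
    sens, spec = [], []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {c} absent from labels; excluded from macro averages")
            continue
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
    out = {
        "sensitivity": float(np.mean(sens)),
        "accuracy": float(np.trace(cm) / n),
        "specificity": float(np.nanmean(spec)),
    }
    if scores is not None and labels is not None:
        out["auroc"] = auroc_ovr(labels, scores)
    return out


def aggregate_folds(per_fold: list[dict]) -> MetricsReport:
    """Mean and population std of each metric over folds."""
    if not per_fold:
        raise ValueError("no folds to aggregate")
    agg = {}
    for name in METRIC_NAMES:
        vals = np.array([f[name] for f in per_fold if name in f], dtype=float)
        agg[name] = (float(vals.mean()), float(vals.std())) if vals.size else (np.nan, np.nan)
    return MetricsReport(**agg)
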