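"""Evaluation metrics and model-comparison statistics.

Classification models are scored with AUC ROC (micro-averaged
one-vs-rest for the categorical head, with macro and per-antigen values
also reported), F1, and false-negative / false-positive rates at a fixed
threshold (0.5 for binary scores, argmax for categorical).  Count models
are scored with R² on log(1+x)-transformed counts.  Model comparisons
use Welch's t-test between two cross-validation sets and the Wilcoxon
rank-sum test across sets of models varying in hyper-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

__all__ = [
    "MetricUndefinedError",
    "EvalReport",
    "auc_roc",
    "multiclass_auc",
    "classification_rates",
    "r2_log",
    "categorical_cross_entropy",
    "msle",
    "compare_models",
]


class MetricUndefinedError(ValueError):
    """The metric is undefined for this input (e.g. single-class AUC)."""


def auc_roc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Binary AUC ROC; raises :class:`MetricUndefinedError` on a
    single-class input instead of reporting a misleading 0."""
    y = np.asarray(y_true)
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError("AUC undefined: test labels contain one class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def multiclass_auc(labels: Sequence[int], probs: np.ndarray) -> dict:
    """One-vs-rest AUCs of a class-probability matrix.

    Returns micro- and macro-averages plus the per-class values (``None``
    where a class is absent from the labels).
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    n_classes = probs.shape[1]
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(labels)), labels] = 1.0
    micro = auc_roc(onehot.ravel(), probs.ravel())
    per_class: dict = {}
    for k in range(n_classes):
        try:
            per_class[k] = auc_roc(onehot[:, k], probs[:, k])
        except MetricUndefinedError:
            per_class[k] = None
    present = [v for v in per_class.values() if v is not None]
    macro = float(np.mean(present)) if present else None
    return {"micro": micro, "macro": macro, "per_class": per_class}


def classification_rates(y_true, y_pred) -> dict:
    """F1 / FNR / FPR from hard labels.

    For multiclass inputs the confusion is aggregated one-vs-rest over
    all classes (micro), matching the micro-averaged AUC convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if len(classes) <= 2 and set(classes) <= {0, 1}:
        tp = np.sum((y_true == 1) & (y_pred == 1))
        fn = np.sum((y_true == 1) & (y_pred == 0))
        fp = np.sum((y_true == 0) & (y_pred == 1))
        tn = np.sum((y_true == 0) & (y_pred == 0))
        f1 = float(f1_score(y_true, y_pred, zero_division=0))
    else:
        tp = fn = fp = tn = 0
        for k in classes:
            tp += np.sum((y_true == k) & (y_pred == k))
            fn += np.sum((y_true == k) & (y_pred != k))
            fp += np.sum((y_true != k) & (y_pred == k))
            tn += np.sum((y_true != k) & (y_pred != k))
        f1 = float(f1_score(y_true, y_pred, average="micro", zero_division=0))
    fnr = float(fn / (fn + tp)) if (fn + tp) else 0.0
    fpr = float(fp / (fp + tn)) if (fp + tn) else 0.0
    return {"f1": f1, "fnr": fnr, "fpr": fpr}


def r2_log(observed_counts, predicted_counts) -> float:
    """R² between log(1+x)-transformed observed and predicted counts,
    computed over all entries (cells × antigens flattened)."""
    y = np.log1p(np.asarray(observed_counts, dtype=float).ravel())
    yhat = np.log1p(np.asarray(predicted_counts, dtype=float).ravel())
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise MetricUndefinedError("R² undefined: observed log-counts are constant")
    return float(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# Losses (public numeric contracts; training uses stabilized logit forms)


def categorical_cross_entropy(predicted: Sequence[float], observed: int) -> float:
    """−log p[observed] for a valid probability vector."""
    p = np.asarray(predicted, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("predicted must be a probability vector summing to 1")
    return float(-np.log(p[observed]))


def msle(predicted_counts, observed_counts) -> float:
    """Mean squared logarithmic error, mean over outputs of
    (log(1+y) − log(1+ŷ))²."""
    yhat = np.asarray(predicted_counts, dtype=float)
    y = np.asarray(observed_counts, dtype=float)
    if np.any(yhat < 0) or np.any(y < 0):
        raise ValueError("msle requires nonnegative counts")
    return float(np.mean((np.log1p(y) - np.log1p(yhat)) ** 2))


# ---------------------------------------------------------------------------
# Reports


@dataclass
class EvalReport:
    """Test-set metrics of one trained model on one fold."""

    auc_roc: Optional[float]
    f1: float
    fnr: float
    fpr: float
    n_test: int
    auc_macro: Optional[float] = None
    auc_per_antigen: dict = field(default_factory=dict)
    r2_log: Optional[float] = None
    r2_per_antigen: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "auc_macro": self.auc_macro,
            "auc_per_antigen": dict(self.auc_per_antigen),
            "f1": self.f1,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "r2_log": self.r2_log,
            "r2_per_antigen": dict(self.r2_per_antigen),
            "n_test": self.n_test,
        }


# ---------------------------------------------------------------------------
# Model comparison


def compare_models(metrics_a: Sequence[float], metrics_b: Sequence[float],
                   mode: str = "welch") -> float:
    """Two-sided p-value comparing two sets of performance metrics.

    ``welch`` — unequal-variance t-test, for two cross-validation sets of
    the same model configuration.  ``wilcoxon`` — rank-sum test (exact
    null distribution for groups of ≤ 10), for sets of models that vary
    in hyper-parameters.  Degenerate Welch inputs (both variances zero)
    return p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    mode = mode.lower()
    if mode == "welch":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("Welch's t-test needs at least 2 values per group")
        if np.var(a) == 0 and np.var(b) == 0:
            return 1.0 if np.mean(a) == np.mean(b) else 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if mode == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("rank-sum test needs non-empty groups")
        method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    raise ValueError(f"unknown comparison mode {mode!r}")
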