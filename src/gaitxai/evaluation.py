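"""Classification metrics, fold aggregation and paired t-tests.

Per-fold metrics are accuracy, macro precision/recall/F1, the multiclass
Matthews correlation coefficient (Gorodkin generalization) and one-vs-rest
AUC per class; model-to-model and experiment-to-experiment comparisons use
a paired t-test on per-fold F1 scores,

    t = mean(d) / (sd(d) / sqrt(n)),   df = n - 1, two-sided p,

with the sample standard deviation (n-1 denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

__all__ = [
    "MetricsReport", "TTestResult", "confusion_matrix",
    "classification_metrics", "matthews_cc", "roc_auc_ovr", "paired_t_test",
    "fold_metrics",
]


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts with entry (i, j) = #(true == i and predicted == j)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if (y_true < 0).any() or (y_true >= n_classes).any() \
            or (y_pred < 0).any() or (y_pred >= n_classes).any():
        raise ValueError(f"labels outside [0, {n_classes})")
    return skm.confusion_matrix(y_true, y_pred,
                                labels=np.arange(n_classes))


def classification_metrics(confusion: np.ndarray) -> dict:
    """Accuracy and macro precision/recall/F1 from a confusion matrix.

    Macro averages are unweighted class means; a class never predicted
    contributes precision 0 (with a warning), mirroring the zero-division
    convention of the underlying library.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = cm.sum()
    tp = np.diag(cm)
    pred_col = cm.sum(axis=0)
    true_row = cm.sum(axis=1)
    if (pred_col == 0).any():
        warnings.warn("some classes were never predicted; their precision "
                      "contributes 0 to the macro average")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_col > 0, tp / np.maximum(pred_col, 1), 0.0)
        recall = np.where(true_row > 0, tp / np.maximum(true_row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall /
                      np.maximum(denom, 1e-300), 0.0)
    return {
        "accuracy": float(tp.sum() / n),
        "precision_macro": float(precision.mean()),
        "recall_macro": float(recall.mean()),
        "f1_macro": float(f1.mean()),
        "precision_per_class": precision,
        "recall_per_class": recall,
        "f1_per_class": f1,
    }


def matthews_cc(confusion: np.ndarray) -> float:
    """Multiclass MCC in [-1, 1]; NaN (flagged) when only one class occurs."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    t = cm.sum(axis=1)   # true counts
    p = cm.sum(axis=0)   # predicted counts
    n = cm.sum()
    if (t > 0).sum() < 2 or (p > 0).sum() < 2:
        warnings.warn("MCC undefined with a single class present; "
                      "returning NaN")
        return float("nan")
    cov_tp = np.trace(cm) * n - t @ p
    cov_tt = n**2 - t @ t
    cov_pp = n**2 - p @ p
    if cov_tt == 0 or cov_pp == 0:
        return float("nan")
    return float(cov_tp / np.sqrt(cov_tt * cov_pp))


def roc_auc_ovr(y_true, proba: np.ndarray) -> np.ndarray:
    """One-vs-rest AUC per class; NaN (flagged) for classes absent in truth."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to one")
    out = np.full(proba.shape[1], np.nan)
    for c in range(proba.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} missing from truth; AUC set to NaN")
            continue
        out[c] = skm.roc_auc_score(pos.astype(int), proba[:, c])
    return out


@dataclass
class TTestResult:
    mean_diff: float
    sd_diff: float
    n: int
    t: float
    p: float
    df: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def paired_t_test(values_a, values_b) -> TTestResult:
    """Two-sided paired t-test on equal-length score vectors.

    Zero-variance differences yield a flagged infinite t (p = 0 if the mean
    difference is nonzero, p = 1 if the samples are identical).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired samples")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return TTestResult(0.0, 0.0, n, 0.0, 1.0, df)
        warnings.warn("zero variance of differences; t is infinite")
        return TTestResult(mean_d, 0.0, n,
                           float(np.sign(mean_d)) * np.inf, 0.0, df)
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(mean_d, sd_d, n, float(t), float(p), df)


@dataclass
class MetricsReport:
    """Per-fold metrics with mean +/- sd aggregation."""

    model: str
    folds: list[dict] = field(default_factory=list)

    def add_fold(self, y_true, proba: np.ndarray, n_classes: int):
        y_true = np.asarray(y_true, dtype=int)
        y_pred = proba.argmax(axis=1)
        cm = confusion_matrix(y_true, y_pred, n_classes)
        m = classification_metrics(cm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m["mcc"] = matthews_cc(cm)
            m["auc_per_class"] = roc_auc_ovr(y_true, proba)
        m["confusion"] = cm
        m["confusion_normalized"] = cm / np.maximum(
            cm.sum(axis=1, keepdims=True), 1)
        m["n_test"] = int(len(y_true))
        self.folds.append(m)
        return m

    def fold_values(self, key: str) -> np.ndarray:
        return np.array([f[key] for f in self.folds], dtype=float)

    def summary(self) -> dict:
        keys = ("accuracy", "precision_macro", "recall_macro", "f1_macro",
                "mcc")
        out = {"model": self.model, "n_folds": len(self.folds)}
        for k in keys:
            v = self.fold_values(k)
            out[f"{k}_mean"] = float(np.nanmean(v))
            out[f"{k}_sd"] = float(np.nanstd(v, ddof=1)) if len(v) > 1 else 0.0
        return out


def fold_metrics(y_true, proba, n_classes: int) -> dict:
    """One-shot fold evaluation (confusion, macro metrics, MCC, AUC)."""
    report = MetricsReport(model="")
    return report.add_fold(y_true, proba, n_classes)
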