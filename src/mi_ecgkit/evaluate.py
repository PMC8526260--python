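"""Confusion matrices, per-class Se/Sp/+p/Acc and stratified k-fold CV.

Per-class metrics follow the one-vs-rest convention: for class c, TP are
beats of c predicted c, FN beats of c predicted otherwise, FP beats of
other classes predicted c, TN the rest.  Then

    Se = TP/(TP+FN)   Sp = TN/(TN+FP)
    +p = TP/(TP+FP)   Acc = (TP+TN)/(TP+TN+FP+FN)

all reported in percent at full precision (rounding is a display choice).
A metric with a zero denominator is reported as NaN (undefined), never 0.

Cross-validation is stratified at beat level by default; anything
trainable (PCA/LPP compressors, the booster) is fitted inside each
training fold only.  Pooled-matrix metrics over the held-out predictions
are primary; per-fold accuracies and their mean are reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from mi_ecgkit.compress import apply_compressors, fit_compressors, fuse_features
from mi_ecgkit.features import FeatureTable
from mi_ecgkit.model import GradientBoostedTreeClassifier

#: fixed reporting order for the ten beat classes
CLASS_ORDER = ["A", "AS", "AL", "I", "IL", "IP", "IPL", "P", "H", "O"]

METRIC_COLUMNS = ["TP", "TN", "FP", "FN", "Se", "Sp", "+p", "Acc"]


def confusion(y_true, y_pred, labels: list[str] | None = None) -> pd.DataFrame:
    """C x C count matrix; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted labels must have equal length")
    if labels is None:
        present = set(y_true) | set(y_pred)
        labels = [c for c in CLASS_ORDER if c in present]
        labels += sorted(present - set(labels))
    else:
        unknown = (set(y_true) | set(y_pred)) - set(labels)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return pd.DataFrame(cm, index=labels, columns=labels)


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def class_metrics(cm: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest TP/TN/FP/FN and Se/Sp/+p/Acc (percent) per class."""
    total = int(cm.values.sum())
    if total <= 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for c in cm.index:
        tp = int(cm.loc[c, c])
        fn = int(cm.loc[c].sum()) - tp
        fp = int(cm[c].sum()) - tp
        tn = total - tp - fn - fp
        rows[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                   "Se": _pct(tp, tp + fn), "Sp": _pct(tn, tn + fp),
                   "+p": _pct(tp, tp + fp),
                   "Acc": _pct(tp + tn, total)}
    return pd.DataFrame(rows).T[METRIC_COLUMNS]


def overall_accuracy(cm: pd.DataFrame) -> float:
    """Trace over total, in percent, at full precision."""
    total = cm.values.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.values) / total


@dataclass
class CVResult:
    """Pooled and per-fold cross-validation results."""

    confusion: pd.DataFrame
    metrics: pd.DataFrame
    pooled_accuracy: float
    fold_accuracies: list[float]
    mean_fold_accuracy: float
    predictions: pd.DataFrame  # columns: fold, true, predicted


def kfold_cv(table: FeatureTable,
             compressor=None,
             feature_set: str = "fused",
             k: int = 10,
             seed: int = 0,
             model: GradientBoostedTreeClassifier | None = None,
             fit_compressor_globally: bool = False,
             groups=None) -> CVResult:
    """Stratified k-fold CV of the full compress->fuse->boost stage.

    ``table`` must carry labels.  Trainable compressors are fitted inside
    each training fold (leak-free); ``fit_compressor_globally=True``
    reproduces the alternative protocol of fitting once on all data.
    ``groups`` (e.g. a record or patient id per beat) switches to
    group-aware folds so beats of one source never straddle a split —
    the honest protocol for per-patient data, where beat-level folds are
    optimistic.
    """
    if table.labels is None:
        raise ValueError("feature table carries no labels")
    labels = np.asarray(table.labels)
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"classes with fewer than k={k} beats: "
            f"{', '.join(too_small.index)}")
    if model is None:
        model = GradientBoostedTreeClassifier(random_state=seed)
    need_comp = feature_set in ("fused", "ventricular")
    if need_comp and compressor is None:
        from mi_ecgkit.compress import DWTCompressor
        compressor = DWTCompressor()

    global_fitted = None
    if need_comp and fit_compressor_globally:
        global_fitted = fit_compressors(table.qt, compressor)

    if groups is not None:
        from sklearn.model_selection import StratifiedGroupKFold

        skf = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        splits = skf.split(np.zeros(len(labels)), labels, groups)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(len(labels)), labels)
    preds = np.empty(len(labels), dtype=labels.dtype)
    fold_of = np.empty(len(labels), dtype=int)
    fold_accs = []
    for fold, (tr, te) in enumerate(splits):
        if need_comp:
            fitted = (global_fitted if global_fitted is not None
                      else fit_compressors(table.qt[tr], compressor))
            comp_tr = apply_compressors(table.qt[tr], fitted)
            comp_te = apply_compressors(table.qt[te], fitted)
        else:
            comp_tr = comp_te = None
        rule_tr = table.rule.iloc[tr] if feature_set != "ventricular" else None
        rule_te = table.rule.iloc[te] if feature_set != "ventricular" else None
        X_tr = fuse_features(rule_tr, comp_tr, table.lead_names, feature_set)
        X_te = fuse_features(rule_te, comp_te, table.lead_names, feature_set)
        est = clone(model).fit(X_tr.values, labels[tr])
        p = est.predict(X_te.values)
        preds[te] = p
        fold_of[te] = fold
        fold_accs.append(float(np.mean(p == labels[te])) * 100.0)
    order = [c for c in CLASS_ORDER if c in set(labels)]
    order += sorted(set(labels) - set(order))
    cm = confusion(labels, preds, labels=order)
    return CVResult(
        confusion=cm,
        metrics=class_metrics(cm),
        pooled_accuracy=overall_accuracy(cm),
        fold_accuracies=fold_accs,
        mean_fold_accuracy=float(np.mean(fold_accs)),
        predictions=pd.DataFrame(
            {"fold": fold_of, "true": labels, "predicted": preds}),
    )


def metrics_report(result: CVResult) -> dict:
    """JSON-ready metrics bundle."""
    return {
        "pooled_accuracy_pct": result.pooled_accuracy,
        "mean_fold_accuracy_pct": result.mean_fold_accuracy,
        "fold_accuracies_pct": result.fold_accuracies,
        "per_class": result.metrics.round(4).to_dict(orient="index"),
        "confusion": {c: result.confusion.loc[c].to_dict()
                      for c in result.confusion.index},
    }
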