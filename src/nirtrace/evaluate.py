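"""Metrics, stratified 10-fold cross-validation, and comparison tables.

Precision/recall/F1 are macro-averaged (unweighted mean over classes) and
reported as percentages to two decimals, the convention of the origin-
traceability literature this package serves.  Cross-validation refits all
train-derived preprocessing state inside each training fold, so no test
information leaks into the folds.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .dataset import SpectraSet, SpectraError, SplitResult
from .preprocess import PreprocessStrategy, fit_apply_strategy
from .selection import WavelengthSubset, apply_subset


@dataclass
class EvalReport:
    confusion: np.ndarray
    accuracy: float            # percent
    macro_precision: float     # percent
    macro_recall: float        # percent
    macro_f1: float            # percent
    per_class_recall: np.ndarray
    n_test: int
    cv_accuracy: float | None = None
    model_tag: str = ""
    preprocess_tag: str = ""
    subset_tag: str = ""


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size != y_pred.size:
        raise SpectraError("label vectors differ in length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise SpectraError(f"{name} label out of range [0, {n_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def classification_metrics(confusion: np.ndarray):
    """(accuracy, macro P, macro R, macro F1, per-class recalls), in percent.

    Classes with a zero row/column sum contribute 0 to the corresponding
    macro average, with a warning.
    """
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    if total == 0:
        raise SpectraError("empty confusion matrix")
    diag = np.diag(C)
    col = C.sum(axis=0)
    row = C.sum(axis=1)
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn("zero-support class; its precision/recall set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    return (
        100.0 * diag.sum() / total,
        100.0 * precision.mean(),
        100.0 * recall.mean(),
        100.0 * f1.mean(),
        100.0 * recall,
    )


def evaluate_predictions(y_true, y_pred, n_classes: int, **tags) -> EvalReport:
    C = confusion_matrix(y_true, y_pred, n_classes)
    acc, mp, mr, mf1, pcr = classification_metrics(C)
    return EvalReport(
        confusion=C, accuracy=acc, macro_precision=mp, macro_recall=mr,
        macro_f1=mf1, per_class_recall=pcr, n_test=int(C.sum()), **tags,
    )


def kfold_cv_accuracy(recipe, X, y, k: int = 10, seed: int = 0):
    """Stratified k-fold CV accuracy of a fit/predict recipe.

    ``recipe`` is a zero-argument factory returning a fresh object with
    ``fit(X, y)`` and ``predict(X)``; any preprocessing the recipe performs
    is refit per fold.  Returns ``(mean_accuracy, per_fold_accuracies)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        raise SpectraError(f"every class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc = []
    for tr, te in skf.split(X, y):
        model = recipe()
        model.fit(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te]))
        fold_acc.append(float((pred == y[te]).mean()))
    return float(np.mean(fold_acc)), fold_acc


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------

def run_comparison(
    split: SplitResult,
    strategies: list[PreprocessStrategy],
    models: dict,
    subsets: list[WavelengthSubset] | None = None,
    cv_folds: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial (strategy x model x subset) evaluation table.

    ``models`` maps a tag to a factory ``() -> estimator`` with
    ``fit(X, y)`` / ``predict(X)``.  Each cell preprocesses the split with
    the strategy (train-fitted state only), applies the wavelength subset,
    fits the model on the training partition, and scores the held-out test
    partition; with ``cv_folds`` set, training-set CV accuracy is added.
    A failing cell is flagged and the remaining cells still run.
    """
    from .selection import full_subset  # local to avoid cycle at import time

    if subsets is None:
        subsets = [full_subset(split.train.n_wavenumbers)]
    rows = []
    n_classes = split.train.n_classes
    for strategy in strategies:
        train_p, test_p, _ = fit_apply_strategy(split.train, split.test, strategy)
        for subset in subsets:
            tr = apply_subset(train_p, subset)
            te = apply_subset(test_p, subset)
            subset_tag = (
                "None" if subset.method == "None" else f"{subset.method}({subset.n_selected})"
            )
            for tag, factory in models.items():
                row = {
                    "strategy": strategy.name,
                    "model": tag,
                    "subset": subset_tag,
                    "failed": False,
                }
                try:
                    t0 = time.perf_counter()
                    model = factory()
                    model.fit(tr.absorbance, tr.labels)
                    pred = np.asarray(model.predict(te.absorbance))
                    train_pred = np.asarray(model.predict(tr.absorbance))
                    fit_seconds = time.perf_counter() - t0
                    report = evaluate_predictions(
                        te.labels, pred, n_classes,
                        model_tag=tag, preprocess_tag=strategy.name,
                        subset_tag=subset_tag,
                    )
                    if cv_folds:
                        cv_acc, _ = kfold_cv_accuracy(
                            factory, tr.absorbance, tr.labels, k=cv_folds, seed=seed
                        )
                        report.cv_accuracy = 100.0 * cv_acc
                    row.update(
                        train_accuracy=100.0 * float((train_pred == tr.labels).mean()),
                        test_accuracy=report.accuracy,
                        macro_precision=report.macro_precision,
                        macro_recall=report.macro_recall,
                        macro_f1=report.macro_f1,
                        cv_accuracy=report.cv_accuracy,
                        fit_seconds=fit_seconds,
                        n_test=report.n_test,
                    )
                except Exception as exc:  # isolate the failing cell
                    row.update(failed=True, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
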