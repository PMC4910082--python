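"""Cross-validated benchmarking of feature sets and classifiers.

The reference protocol is 10-fold cross validation without explicit
stratification: the samples are randomly partitioned into 10 parts of
(near-)equal size; each part serves once as the test set while the
classifier — including its feature standardizer — is fitted on the
remaining nine.  Accuracy is the mean of the per-fold accuracies.

A full benchmark crosses feature sets x classifier kinds x problems
(two-class tumour-vs-stroma and the 8-class problem), 4 x 6 x 2 = 48
experiments in the reference configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .classify import ClassifierSpec, _as_matrix, train_classifier
from .features import extract_matrix

__all__ = [
    "CVResult",
    "kfold_split",
    "cross_validate",
    "confusion_matrix",
    "roc_one_vs_all",
    "run_benchmark",
]


def kfold_split(n: int, k: int, seed: int) -> np.ndarray:
    """Random fold assignment 0..k-1 per sample; fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % k
    rng.shuffle(assignment)
    return assignment


@dataclass
class CVResult:
    """Outcome of one k-fold cross validation run."""

    fold_accuracies: np.ndarray
    pooled_confusion: np.ndarray
    pooled_scores: np.ndarray
    fold_assignment: np.ndarray
    class_ids: np.ndarray
    predictions: np.ndarray = field(default=None)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts with entry (i, j) = true class i+1 predicted as class j+1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if len(y) and (y.min() < 1 or y.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


def cross_validate(X, y, spec: ClassifierSpec, k: int = 10,
                   seed: int = 0, repeats: int = 1) -> CVResult:
    """k-fold CV fitting standardizer + classifier on training folds only.

    With ``repeats`` > 1 the random subdivision is redrawn that many
    times; fold accuracies concatenate across repeats, the pooled
    confusion matrix sums over repeats and the pooled scores are
    averaged, so every sample is tested exactly once *per repeat*.
    """
    if repeats > 1:
        runs = [cross_validate(X, y, spec, k=k, seed=seed + 7919 * r)
                for r in range(repeats)]
        return CVResult(
            fold_accuracies=np.concatenate(
                [r.fold_accuracies for r in runs]
            ),
            pooled_confusion=np.sum(
                [r.pooled_confusion for r in runs], axis=0
            ),
            pooled_scores=np.mean([r.pooled_scores for r in runs], axis=0),
            fold_assignment=runs[0].fold_assignment,
            class_ids=runs[0].class_ids,
            predictions=runs[0].predictions,
        )
    arr, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    n = len(y)
    class_ids = np.unique(y)
    folds = kfold_split(n, k, seed)
    accuracies = np.empty(k)
    scores = np.zeros((n, len(class_ids)))
    predictions = np.zeros(n, dtype=int)
    col = {c: i for i, c in enumerate(class_ids)}
    for f in range(k):
        test = folds == f
        train = ~test
        train_classes = np.unique(y[train])
        if len(train_classes) < len(class_ids):
            warnings.warn(
                f"fold {f}: training folds miss "
                f"{len(class_ids) - len(train_classes)} class(es)"
            )
        clf = train_classifier(
            pd.DataFrame(arr[train], columns=names), y[train], spec
        )
        fold_scores = clf.predict_scores(
            pd.DataFrame(arr[test], columns=names)
        )
        pred = clf.class_ids[np.argmax(fold_scores, axis=1)]
        predictions[test] = pred
        cols = [col[c] for c in clf.class_ids]
        scores[np.ix_(np.nonzero(test)[0], cols)] = fold_scores
        accuracies[f] = float(np.mean(pred == y[test]))
    cm = confusion_matrix(y, predictions, int(class_ids.max()))
    # keep only the rows/cols of classes actually present
    present = class_ids - 1
    cm = cm[np.ix_(present, present)]
    return CVResult(
        fold_accuracies=accuracies,
        pooled_confusion=cm,
        pooled_scores=scores,
        fold_assignment=folds,
        class_ids=class_ids,
        predictions=predictions,
    )


def roc_one_vs_all(scores: np.ndarray, y) -> dict:
    """Per-class one-vs-all ROC curves and AUCs, plus their macro mean.

    ``scores[:, c]`` is the committee score for class ``class_ids[c]``;
    class ids are taken as 1..scores.shape[1].  Classes absent from
    ``y`` are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    out = {"curves": {}, "aucs": {}}
    for c in range(scores.shape[1]):
        cid = c + 1
        positive = y == cid
        if not positive.any() or positive.all():
            warnings.warn(f"class {cid} lacks positives or negatives; skipped")
            continue
        fpr, tpr, _ = _roc_curve(positive.astype(int), scores[:, c])
        out["curves"][cid] = (fpr, tpr)
        out["aucs"][cid] = float(_auc(fpr, tpr))
    out["mean_auc"] = (float(np.mean(list(out["aucs"].values())))
                       if out["aucs"] else float("nan"))
    return out


def run_benchmark(
    tileset,
    feature_sets,
    classifier_specs,
    problems=("two_class", "multi_class"),
    k: int = 10,
    seed: int = 0,
    two_class_names=None,
) -> pd.DataFrame:
    """Cross the full grid of feature sets x classifiers x problems.

    Returns a DataFrame with one row per experiment carrying the mean CV
    accuracy and error.  ``two_class_names`` defaults to the first two
    class names of the tile set (tumour epithelium and simple stroma in
    the reference ordering).
    """
    if two_class_names is None:
        two_class_names = tileset.class_names[:2]
    problem_sets = {}
    for problem in problems:
        if problem == "two_class":
            problem_sets[problem] = tileset.subset_by_class_names(
                two_class_names
            )
        elif problem == "multi_class":
            problem_sets[problem] = tileset
        else:
            raise ValueError(f"unknown problem {problem!r}")

    rows = []
    for feature_set in feature_sets:
        matrices = {
            problem: extract_matrix(ts, feature_set)
            for problem, ts in problem_sets.items()
        }
        for spec in classifier_specs:
            for problem in problems:
                df = matrices[problem]
                result = cross_validate(
                    df, df["label"].to_numpy(), spec, k=k, seed=seed
                )
                rows.append({
                    "feature_set": feature_set,
                    "classifier": spec.kind,
                    "problem": problem,
                    "mean_accuracy": result.mean_accuracy,
                    "error_rate": 1.0 - result.mean_accuracy,
                })
    return pd.DataFrame(rows)
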