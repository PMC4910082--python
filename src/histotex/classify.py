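"""Classifiers for texture feature vectors behind one uniform contract.

Four classifier kinds are supported:

* ``nn1`` — Euclidean 1-nearest-neighbour on standardized features.
* ``linear_svm`` / ``rbf_svm`` — one-versus-one binary SVMs combined by
  error-correcting output code (ECOC) decoding: per candidate class the
  hinge losses of the binary margins are aggregated over the pairs the
  class takes part in, and the class with the smallest aggregate loss
  wins.  Committee scores are the softmax of the negated aggregate
  losses, so each row is a probability-like vector summing to one.
* ``rusboost`` — a boosted ensemble of shallow decision trees in which
  each boosting round trains on a class-balanced random undersample
  (RUS) of the data; weights follow the multiclass SAMME update.

Feature standardization (per-column zero mean, unit population sd) is
learned together with the classifier and applied identically at
prediction time; constant columns get sd = 1 so they transform to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Standardizer",
    "ClassifierSpec",
    "TrainedClassifier",
    "train_classifier",
    "save_model",
    "load_model",
]

CLASSIFIER_KINDS = ("nn1", "linear_svm", "rbf_svm", "rusboost")

_MODEL_FORMAT_VERSION = 1


def _as_matrix(X, feature_names=None):
    """Accept a DataFrame (optionally with a label column) or an array."""
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c != "label"]
        return X[cols].to_numpy(dtype=np.float64), cols
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(arr.shape[1])]
    return arr, list(feature_names)


@dataclass
class Standardizer:
    """Per-column centering/scaling parameters (population sd)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer needs a 2-D matrix with >= 2 rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population (n) convention
        sd = np.where(sd > 0, sd, 1.0)  # constant columns -> zeros
        return cls(mean=mean, sd=sd)

    @classmethod
    def identity(cls, n_features: int) -> "Standardizer":
        return cls(mean=np.zeros(n_features), sd=np.ones(n_features))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.sd


def fit_standardizer(X) -> Standardizer:
    arr, _ = _as_matrix(X)
    return Standardizer.fit(arr)


@dataclass
class ClassifierSpec:
    """Recipe for one classifier: kind + hyperparameters + seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; "
                f"expected one of {CLASSIFIER_KINDS}"
            )


class _OvoEcocSVM:
    """One-vs-one SVMs with hinge-loss ECOC decoding."""

    def __init__(self, kernel, C=1.0, gamma=None):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.pairs_ = []
        self.learners_ = []

    def fit(self, X, y, class_ids):
        self.class_ids_ = np.asarray(class_ids)
        idx = {c: i for i, c in enumerate(self.class_ids_)}
        for a in range(len(self.class_ids_)):
            for b in range(a + 1, len(self.class_ids_)):
                ca, cb = self.class_ids_[a], self.class_ids_[b]
                mask = (y == ca) | (y == cb)
                yy = np.where(y[mask] == ca, 1, -1)
                gamma = self.gamma if self.gamma is not None else "scale"
                svc = SVC(kernel=self.kernel, C=self.C, gamma=gamma)
                svc.fit(X[mask], yy)
                self.pairs_.append((idx[ca], idx[cb]))
                self.learners_.append(svc)
        return self

    def aggregate_losses(self, X):
        n, k = X.shape[0], len(self.class_ids_)
        losses = np.zeros((n, k))
        counts = np.zeros(k)
        for (a, b), svc in zip(self.pairs_, self.learners_):
            f = svc.decision_function(X)
            # margin sign: +1 for class a, -1 for class b
            losses[:, a] += np.maximum(0.0, 1.0 - f) / 2.0
            losses[:, b] += np.maximum(0.0, 1.0 + f) / 2.0
            counts[a] += 1
            counts[b] += 1
        return losses / np.maximum(counts, 1)

    def scores(self, X):
        loss = self.aggregate_losses(X)
        z = -loss
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class _RUSBoost:
    """SAMME boosting of shallow trees on balanced random undersamples."""

    def __init__(self, n_estimators=100, max_depth=5, learning_rate=0.1,
                 seed=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.seed = seed
        self.trees_ = []
        self.alphas_ = []

    def fit(self, X, y, class_ids):
        self.class_ids_ = np.asarray(class_ids)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        k = len(self.class_ids_)
        w = np.full(n, 1.0 / n)
        min_count = min(int(np.sum(y == c)) for c in self.class_ids_)
        by_class = {c: np.nonzero(y == c)[0] for c in self.class_ids_}
        for t in range(self.n_estimators):
            sel = np.concatenate([
                rng.choice(by_class[c], size=min_count, replace=False)
                for c in self.class_ids_
            ])
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            sw = w[sel]
            tree.fit(X[sel], y[sel], sample_weight=sw / sw.sum())
            pred = tree.predict(X)
            miss = pred != y
            err = float(np.sum(w[miss]) / np.sum(w))
            err = min(max(err, 1e-10), 1.0 - 1.0 / k - 1e-10)
            alpha = self.learning_rate * (
                np.log((1.0 - err) / err) + np.log(k - 1.0)
            )
            self.trees_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * miss)
            w /= w.sum()
        return self

    def scores(self, X):
        n, k = X.shape[0], len(self.class_ids_)
        votes = np.zeros((n, k))
        col = {c: i for i, c in enumerate(self.class_ids_)}
        for tree, alpha in zip(self.trees_, self.alphas_):
            pred = tree.predict(X)
            for c in self.class_ids_:
                votes[pred == c, col[c]] += alpha
        total = votes.sum(axis=1, keepdims=True)
        flat = total[:, 0] <= 0
        if flat.any():
            votes[flat] = 1.0
            total = votes.sum(axis=1, keepdims=True)
        return votes / total


@dataclass
class TrainedClassifier:
    """A fitted model bundled with its standardization and metadata."""

    spec: ClassifierSpec
    standardizer: Standardizer
    model: object
    class_ids: np.ndarray
    feature_names: list

    def _prepare(self, X):
        arr, names = _as_matrix(X, self.feature_names)
        if names != self.feature_names:
            raise ValueError(
                "feature columns do not match the training columns"
            )
        if arr.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, "
                f"got {arr.shape[1]}"
            )
        return self.standardizer.transform(arr)

    def predict_scores(self, X) -> np.ndarray:
        """Per-class committee scores; rows sum to 1."""
        Z = self._prepare(X)
        kind = self.spec.kind
        if kind == "nn1":
            pred = self.model.predict(Z)
            scores = np.zeros((len(Z), len(self.class_ids)))
            col = {c: i for i, c in enumerate(self.class_ids)}
            for c in self.class_ids:
                scores[pred == c, col[c]] = 1.0
            return scores
        return self.model.scores(Z)

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        return self.class_ids[np.argmax(scores, axis=1)]


def train_classifier(X, y, spec: ClassifierSpec,
                     standardize: bool = True) -> TrainedClassifier:
    """Fit one classifier (with its standardizer) on a feature matrix."""
    arr, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if arr.shape[0] != len(y):
        raise ValueError("X and y have different numbers of rows")
    bad = np.nonzero(~np.isfinite(arr).all(axis=0))[0]
    if bad.size:
        raise ValueError(
            f"non-finite values in feature column(s): "
            f"{[names[i] for i in bad]}"
        )
    class_ids = np.unique(y)
    if len(class_ids) < 2:
        raise ValueError("training data contains a single class")
    standardizer = (Standardizer.fit(arr) if standardize
                    else Standardizer.identity(arr.shape[1]))
    Z = standardizer.transform(arr)

    hp = dict(spec.hyperparameters)
    if spec.kind == "nn1":
        model = KNeighborsClassifier(n_neighbors=1).fit(Z, y)
    elif spec.kind in ("linear_svm", "rbf_svm"):
        C = hp.get("C", 1.0)
        if spec.kind == "linear_svm":
            model = _OvoEcocSVM(kernel="linear", C=C)
        else:
            # rbf kernel scale sqrt(d)  <=>  gamma = 1 / d
            kernel_scale = hp.get("kernel_scale",
                                  float(np.sqrt(Z.shape[1])))
            model = _OvoEcocSVM(kernel="rbf", C=C,
                                gamma=1.0 / kernel_scale**2)
        model.fit(Z, y, class_ids)
    elif spec.kind == "rusboost":
        model = _RUSBoost(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 5),
            learning_rate=hp.get("learning_rate", 0.1),
            seed=spec.seed,
        ).fit(Z, y, class_ids)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.kind)
    return TrainedClassifier(
        spec=spec,
        standardizer=standardizer,
        model=model,
        class_ids=class_ids,
        feature_names=names,
    )


def save_model(path, clf: TrainedClassifier, extractor_config=None) -> None:
    """Persist a trained classifier as a versioned archive."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "spec": {"kind": clf.spec.kind,
                 "hyperparameters": clf.spec.hyperparameters,
                 "seed": clf.spec.seed},
        "standardizer": {"mean": clf.standardizer.mean,
                         "sd": clf.standardizer.sd},
        "class_ids": clf.class_ids,
        "feature_names": clf.feature_names,
        "extractor_config": extractor_config or {},
        "model": clf.model,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedClassifier:
    """Load a persisted classifier, verifying the archive contents."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise OSError(f"cannot load model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a histotex model archive")
    if payload["format_version"] != _MODEL_FORMAT_VERSION:
        warnings.warn(
            f"model format version {payload['format_version']} differs "
            f"from current {_MODEL_FORMAT_VERSION}"
        )
    names = payload["feature_names"]
    if not isinstance(names, list) or not names:
        raise ValueError(f"{path} carries no feature-name list")
    return TrainedClassifier(
        spec=ClassifierSpec(**payload["spec"]),
        standardizer=Standardizer(**payload["standardizer"]),
        model=payload["model"],
        class_ids=np.asarray(payload["class_ids"]),
        feature_names=names,
    )
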