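"""Classifiers, stratified cross-validation, and confusion-based metrics.

Three binary classifiers are evaluated on each feature regime: k-nearest
neighbors (Euclidean distance, majority vote), a Gini decision tree, and a
soft-margin linear SVM (min 1/2 ||w||^2 + C sum xi_i).  Evaluation uses
stratified k-fold cross-validation (default k=5) and reports accuracy and
sensitivity in percent plus the F1 score, both per fold and pooled over the
concatenated test folds.  The geo-authentic class is the positive class.

Decision trees and the linear SVM are fitted through scikit-learn; the KNN
vote and its deterministic tie-break, the fold dealer, and the metric
arithmetic are implemented here.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ModelError, ParameterError
from .imaging import RenderSpec, rasterize_dataset
from .preprocess import PreprocessSpec, apply, experiment_spec
from .synth import GEO_AUTHENTIC, Dataset
from .texture import LBPConfig, LBPHistogram

logger = logging.getLogger(__name__)

REGIMES = ("exp1_raw", "exp2_preprocessed", "exp3_lbp")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and its (few) hyperparameters.

    ``knn_k`` defaults to 5; ``svm_c`` to 1.0 (the linear kernel leaves only
    the penalty C); the tree uses Gini impurity, unlimited depth and
    min_samples_leaf=1 unless overridden.
    """

    kind: str = "svm"
    knn_k: int = 5
    svm_c: float = 1.0
    dt_max_depth: int | None = None
    dt_min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "dt", "svm"):
            raise ParameterError(f"kind must be knn, dt or svm, got {self.kind!r}")
        if self.knn_k < 1:
            raise ParameterError(f"knn_k must be >= 1, got {self.knn_k}")
        if not self.svm_c > 0:
            raise ParameterError(f"svm_c must be > 0, got {self.svm_c}")


def euclidean_distance(x1, x2) -> float:
    """d = sqrt(sum_i (x_i^1 - x_i^2)^2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ParameterError(f"length mismatch: {x1.shape} vs {x2.shape}")
    return float(np.sqrt(np.sum((x1 - x2) ** 2)))


def _check_training(X, y, require_both_classes: bool = True):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ModelError("empty training set")
    if X.shape[0] != y.shape[0]:
        raise ParameterError("X and y lengths differ")
    classes = np.unique(y)
    if require_both_classes and classes.size < 2:
        raise ModelError("training data contains a single class")
    return X, y, classes


class KNNClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbor majority vote under Euclidean distance.

    Vote ties (possible for even k) are broken deterministically: the tied
    class whose neighbors among the k are *nearer* in summed distance wins;
    a residual tie falls to label sort order.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X, y, classes = _check_training(X, y)
        if self.n_neighbors > X.shape[0]:
            raise ModelError(
                f"n_neighbors={self.n_neighbors} exceeds training size {X.shape[0]}"
            )
        self.classes_ = classes
        self._X = X
        self._y = y
        self._nn = NearestNeighbors(n_neighbors=self.n_neighbors, metric="euclidean").fit(X)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        dist, idx = self._nn.kneighbors(X)
        out = np.empty(X.shape[0], dtype=self._y.dtype)
        for i in range(X.shape[0]):
            nb_labels = self._y[idx[i]]
            nb_dist = dist[i]
            best = None
            for c in self.classes_:  # classes_ is sorted: label-order fallback
                mask = nb_labels == c
                votes = int(mask.sum())
                key = (-votes, float(nb_dist[mask].sum()) if votes else np.inf)
                if best is None or key < best[0]:
                    best = (key, c)
            out[i] = best[1]
        return out


class LinearSVM(SVC):
    """Soft-margin linear SVM (SVC with a fixed linear kernel)."""

    def __init__(self, C: float = 1.0):
        super().__init__(C=C, kernel="linear")

    def fit(self, X, y, sample_weight=None):
        _check_training(X, y)
        return super().fit(X, y, sample_weight)

    @property
    def w_(self) -> np.ndarray:
        return np.asarray(self.coef_).ravel()

    @property
    def b_(self) -> float:
        return float(self.intercept_[0])


def make_classifier(spec: ClassifierSpec):
    if spec.kind == "knn":
        return KNNClassifier(n_neighbors=spec.knn_k)
    if spec.kind == "dt":
        return DecisionTreeClassifier(
            criterion="gini",
            max_depth=spec.dt_max_depth,
            min_samples_leaf=spec.dt_min_leaf,
            random_state=spec.seed,
        )
    return LinearSVM(C=spec.svm_c)


def knn_train(X, y, spec: ClassifierSpec = ClassifierSpec(kind="knn")):
    return KNNClassifier(n_neighbors=spec.knn_k).fit(X, y)


def knn_predict(model, X):
    return model.predict(np.asarray(X, dtype=float))


def dt_train(X, y, spec: ClassifierSpec = ClassifierSpec(kind="dt"), require_both_classes: bool = True):
    X, y, _ = _check_training(X, y, require_both_classes)
    return DecisionTreeClassifier(
        criterion="gini",
        max_depth=spec.dt_max_depth,
        min_samples_leaf=spec.dt_min_leaf,
        random_state=spec.seed,
    ).fit(X, y)


def dt_predict(model, X):
    return model.predict(np.asarray(X, dtype=float))


def svm_train(X, y, spec: ClassifierSpec = ClassifierSpec(kind="svm")):
    return LinearSVM(C=spec.svm_c).fit(X, y)


def svm_predict(model, X):
    return model.predict(np.asarray(X, dtype=float))


@dataclass
class FoldAssignment:
    """fold_index[i] in 0..k-1 for every sample."""

    fold_index: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def stratified_kfold(labels, k: int, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment: per-class shuffle, then a single
    round-robin deal across classes so per-class fold sizes differ by <= 1
    and overall fold sizes are as even as possible."""
    labels = np.asarray(labels)
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    fold = np.empty(labels.shape[0], dtype=int)
    rng = np.random.default_rng(seed)
    pointer = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ParameterError(
                f"class {c!r} has {idx.size} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for i in idx:
            fold[i] = pointer % k
            pointer += 1
    return FoldAssignment(fold, k)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )


def confusion(y_true, y_pred, positive_label=GEO_AUTHENTIC) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred lengths differ")
    classes = set(np.unique(y_true)) | set(np.unique(y_pred))
    if positive_label not in classes:
        raise ParameterError(f"positive label {positive_label!r} absent from labels")
    if len(classes) > 2:
        raise ParameterError(f"expected two classes, got {sorted(map(str, classes))}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
    )


@dataclass(frozen=True)
class Metrics:
    """ACC and SEN in percent; PRE, REC and F1 as fractions (SEN = 100*REC)."""

    acc: float
    sen: float
    pre: float
    rec: float
    f1: float


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """ACC = (TP+TN)/total * 100; SEN = REC*100 with REC = TP/(TP+FN);
    PRE = TP/(TP+FP); F1 = 2*PRE*REC/(PRE+REC).  Any 0/0 is defined as 0
    (logged)."""
    if counts.total == 0:
        raise ParameterError("cannot compute metrics on zero samples")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s is 0/0; defined as 0", name)
            return 0.0
        return num / den

    acc = (counts.tp + counts.tn) / counts.total * 100.0
    rec = ratio(counts.tp, counts.tp + counts.fn, "recall")
    pre = ratio(counts.tp, counts.tp + counts.fp, "precision")
    if pre + rec == 0:
        logger.warning("F1 is 0/0; defined as 0")
        f1 = 0.0
    else:
        f1 = 2.0 * pre * rec / (pre + rec)
    return Metrics(acc=acc, sen=100.0 * rec, pre=pre, rec=rec, f1=f1)


@dataclass
class EvaluationReport:
    """Per-fold and pooled cross-validation results for one regime/classifier."""

    regime: str
    classifier: str
    k: int
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[Metrics]
    pooled_counts: ConfusionCounts
    pooled_metrics: Metrics
    fold_mean_metrics: Metrics
    train_predict_seconds: float
    seed: int = 0
    n_features: int = 0

    def to_dict(self) -> dict:
        def m(x: Metrics) -> dict:
            return {"acc": x.acc, "sen": x.sen, "pre": x.pre, "rec": x.rec, "f1": x.f1}

        def c(x: ConfusionCounts) -> dict:
            return {"tp": x.tp, "fn": x.fn, "tn": x.tn, "fp": x.fp}

        return {
            "regime": self.regime,
            "classifier": self.classifier,
            "k": self.k,
            "seed": self.seed,
            "n_features": self.n_features,
            "folds": [
                {"counts": c(cc), "metrics": m(mm)}
                for cc, mm in zip(self.fold_counts, self.fold_metrics)
            ],
            "pooled": {"counts": c(self.pooled_counts), "metrics": m(self.pooled_metrics)},
            "fold_mean": m(self.fold_mean_metrics),
            "train_predict_seconds": self.train_predict_seconds,
        }

    def summary_row(self) -> dict:
        return {
            "regime": self.regime,
            "classifier": self.classifier,
            "accuracy_pct": round(self.pooled_metrics.acc, 2),
            "sensitivity_pct": round(self.pooled_metrics.sen, 2),
            "f1_score": round(self.pooled_metrics.f1, 4),
            "seconds": round(self.train_predict_seconds, 4),
        }


def build_features(
    dataset: Dataset,
    regime: str,
    preprocess_spec: PreprocessSpec | None = None,
    render_spec: RenderSpec | None = None,
    lbp_config: LBPConfig | None = None,
) -> np.ndarray:
    """Feature matrix for a regime: raw cropped vectors (exp1), solvent-
    excised vectors (exp2), or riu2 LBP histograms of rendered images (exp3)."""
    if regime not in REGIMES:
        raise ParameterError(f"unknown regime {regime!r}; choose from {REGIMES}")
    if preprocess_spec is None:
        preprocess_spec = experiment_spec(1 if regime == "exp1_raw" else 2)
    ds = apply(preprocess_spec, dataset)
    if regime in ("exp1_raw", "exp2_preprocessed"):
        return ds.X
    render_spec = render_spec or RenderSpec()
    lbp_config = lbp_config or LBPConfig()
    images = rasterize_dataset(ds, render_spec)
    extractor = LBPHistogram(
        r=lbp_config.r, p=lbp_config.p, mode=lbp_config.mode,
        interpolation=lbp_config.interpolation,
    )
    return extractor.fit_transform(np.stack([im.pixels for im in images]))


def cross_validate(
    features: np.ndarray,
    labels,
    classifier_spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    regime: str = "",
    positive_label=GEO_AUTHENTIC,
) -> EvaluationReport:
    """Stratified k-fold CV of one classifier on a precomputed feature
    matrix; wall time covers training + prediction only."""
    labels = np.asarray(labels)
    folds = stratified_kfold(labels, k, seed)
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[Metrics] = []
    elapsed = 0.0
    for f in range(k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        clf = make_classifier(replace(classifier_spec, seed=classifier_spec.seed + f))
        t0 = time.perf_counter()
        clf.fit(features[tr], labels[tr])
        pred = clf.predict(features[te])
        elapsed += time.perf_counter() - t0
        cc = confusion(labels[te], pred, positive_label)
        fold_counts.append(cc)
        fold_metrics.append(compute_metrics(cc))
    pooled = fold_counts[0]
    for cc in fold_counts[1:]:
        pooled = pooled + cc
    mean = Metrics(
        acc=float(np.mean([m.acc for m in fold_metrics])),
        sen=float(np.mean([m.sen for m in fold_metrics])),
        pre=float(np.mean([m.pre for m in fold_metrics])),
        rec=float(np.mean([m.rec for m in fold_metrics])),
        f1=float(np.mean([m.f1 for m in fold_metrics])),
    )
    return EvaluationReport(
        regime=regime,
        classifier=classifier_spec.kind,
        k=k,
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        pooled_counts=pooled,
        pooled_metrics=compute_metrics(pooled),
        fold_mean_metrics=mean,
        train_predict_seconds=elapsed,
        seed=seed,
        n_features=features.shape[1],
    )


def run_experiment(
    dataset: Dataset,
    regime: str,
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    k: int = 5,
    seed: int = 0,
    preprocess_spec: PreprocessSpec | None = None,
    render_spec: RenderSpec | None = None,
    lbp_config: LBPConfig | None = None,
) -> EvaluationReport:
    """End-to-end evaluation of one regime: build features, run stratified
    k-fold CV, return the report (features are deterministic per sample, so
    they are computed once outside the fold loop)."""
    if any(lab is None for lab in dataset.labels):
        raise ParameterError("run_experiment requires a fully labeled dataset")
    features = build_features(dataset, regime, preprocess_spec, render_spec, lbp_config)
    return cross_validate(
        features, dataset.labels, classifier_spec, k=k, seed=seed, regime=regime
    )


def write_summary_csv(path: str | Path, reports) -> None:
    """Flat summary, one row per report (Accuracy %, Sensitivity %, F1)."""
    pd.DataFrame([r.summary_row() for r in reports]).to_csv(Path(path), index=False)
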