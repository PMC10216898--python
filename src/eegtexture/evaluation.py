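"""Classifier evaluation under repeated k-fold and leave-one-out CV.

Three classifiers are evaluated, at fixed, untuned settings: a linear
SVM (box constraint 1), a 1-nearest-neighbor classifier (Euclidean), and
a feed-forward network with a single hidden layer of 10 ReLU units.

Inside every training fold — and only there — the chi-square feature
ranking is fitted, the top-k features are selected, and z-score
standardization parameters are estimated, so no statistic of the test
subjects ever reaches the model (a "global" selection mode that ranks on
the full table exists for diagnostics and is explicitly leaky). Folds
are stratified by default, the whole partition is redrawn ``n_repeats``
times, and metrics are pooled over folds within each repetition; the
summary reports each metric's mean and (min-max) range across
repetitions.

Six metrics are reported: ACC, SENS, SPEC, PPV, NPV from the pooled
confusion matrix, and AUC from continuous decision scores (signed
distance to the hyperplane for the SVM, difference of nearest-neighbor
distances for 1-NN, output activation for the network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import FeatureTable
from .selection import Chi2TopK, chi2_scores, select_top_k

__all__ = [
    "METRIC_NAMES",
    "ClassifierSpec",
    "CVScheme",
    "ConfusionMatrix",
    "CVReport",
    "NearestNeighborClassifier",
    "make_classifier",
    "build_pipeline",
    "compute_metrics",
    "run_cv",
    "audit_fold_selection",
]

METRIC_NAMES = ("AUC", "ACC", "SENS", "SPEC", "PPV", "NPV")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run, at its fixed default settings.

    kinds: ``svm_linear`` (linear kernel, box constraint 1, kernel scale
    1), ``knn1`` (1 neighbor, Euclidean), ``ffnet`` (one hidden layer of
    10 ReLU units). ``standardize`` controls per-fold z-scoring of the
    selected features.
    """

    kind: str = "svm_linear"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_linear", "knn1", "ffnet"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout.

    ``repeated_kfold`` redraws a (stratified) k-fold partition
    ``n_repeats`` times; ``loocv`` holds out each subject once and is
    deterministic, so it runs a single repetition.
    """

    kind: str = "repeated_kfold"
    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("repeated_kfold", "loocv"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "repeated_kfold" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive class = 1)."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.tn + other.tn, self.fp + other.fp,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


class NearestNeighborClassifier(ClassifierMixin, BaseEstimator):
    """1-nearest-neighbor classifier with a continuous decision score.

    Predicts the class of the Euclidean-nearest training point. The
    decision score is ``d0 - d1``, the distance to the nearest class-0
    point minus the distance to the nearest class-1 point: positive
    means closer to class 1. A hard 1-NN label carries no ranking
    information, and a continuous score is required for AUC.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("NearestNeighborClassifier is binary")
        self._nn = {
            c: NearestNeighbors(n_neighbors=1).fit(X[y == c]) for c in self.classes_
        }
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "_nn")
        X = np.asarray(X, dtype=float)
        d0 = self._nn[self.classes_[0]].kneighbors(X)[0][:, 0]
        d1 = self._nn[self.classes_[1]].kneighbors(X)[0][:, 0]
        return d0 - d1

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.classes_[1], self.classes_[0])


def make_classifier(spec: ClassifierSpec) -> BaseEstimator:
    """Instantiate the classifier named by a spec."""
    if spec.kind == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if spec.kind == "knn1":
        return NearestNeighborClassifier()
    # max_iter raised above the sklearn default so the optimizer actually
    # converges on the small per-fold training sets typical here
    return MLPClassifier(
        hidden_layer_sizes=(10,), activation="relu", random_state=spec.seed,
        max_iter=1000,
    )


def build_pipeline(spec: ClassifierSpec, k_features: int, n_bins: int = 10) -> Pipeline:
    """Per-fold pipeline: chi-square top-k -> (z-score) -> classifier."""
    steps: list[tuple[str, BaseEstimator]] = [
        ("select", Chi2TopK(k=k_features, n_bins=n_bins))
    ]
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", make_classifier(spec)))
    return Pipeline(steps)


def _decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    clf = model.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def compute_metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> dict[str, float]:
    """ACC/SENS/SPEC/PPV/NPV from counts; AUC from decision scores.

    Ratios with a zero denominator are reported as NaN with a warning.
    AUC is the rank-based area under the ROC (midrank tie handling) and
    is NaN when scores are absent or the test set has a single class.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            return float("nan")
        return num / den

    metrics = {
        "ACC": (cm.tp + cm.tn) / cm.total,
        "SENS": ratio(cm.tp, cm.tp + cm.fn, "SENS"),
        "SPEC": ratio(cm.tn, cm.tn + cm.fp, "SPEC"),
        "PPV": ratio(cm.tp, cm.tp + cm.fp, "PPV"),
        "NPV": ratio(cm.tn, cm.tn + cm.fn, "NPV"),
    }
    if scores is None or y_true is None:
        warnings.warn("no decision scores available; AUC omitted (NaN)")
        metrics["AUC"] = float("nan")
    elif np.unique(y_true).size < 2:
        warnings.warn("single class in test labels; AUC undefined (NaN)")
        metrics["AUC"] = float("nan")
    else:
        metrics["AUC"] = float(roc_auc_score(y_true, scores))
    return metrics


@dataclass
class CVReport:
    """Everything one CV run produced.

    ``per_repeat[r]`` holds the repetition's folds (test indices,
    predictions, decision scores, selected feature indices, confusion
    matrix) and its pooled metrics. ``summary[metric]`` is the mean and
    min-max range of the pooled metric across repetitions.
    """

    per_repeat: list[dict] = field(default_factory=list)
    summary: dict[str, dict[str, float]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def summary_line(self) -> str:
        parts = [
            f"{m}={s['mean']:.4f} ({s['min']:.4f}-{s['max']:.4f})"
            for m, s in self.summary.items()
        ]
        return " ".join(parts)


def _make_splitter(scheme: CVScheme, rep: int):
    if scheme.kind == "loocv":
        return LeaveOneOut()
    cls = StratifiedKFold if scheme.stratified else KFold
    return cls(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed + rep)


def run_cv(
    tbl: FeatureTable,
    clf: ClassifierSpec | None = None,
    scheme: CVScheme | None = None,
    k_features: int = 1000,
    n_bins: int = 10,
    selection_mode: str = "per_fold",
) -> CVReport:
    """Evaluate one classifier on a feature table under one CV scheme.

    ``selection_mode='per_fold'`` (the default) refits the chi-square
    ranking and the standardization inside every training fold.
    ``'global'`` ranks once on the full table before splitting — it
    leaks test information into selection and exists only to measure
    the size of that leak.
    """
    clf = clf or ClassifierSpec()
    scheme = scheme or CVScheme()
    if selection_mode not in ("per_fold", "global"):
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    X, y = tbl.values, tbl.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("evaluation requires exactly two classes")
    if not 1 <= k_features <= tbl.n_features:
        raise ValueError(f"k_features must be in 1..{tbl.n_features}")
    if scheme.kind == "repeated_kfold" and counts.min() < scheme.n_folds:
        if scheme.stratified:
            raise ValueError(
                f"smallest class has {counts.min()} subjects; cannot stratify "
                f"{scheme.n_folds} folds"
            )

    global_keep: np.ndarray | None = None
    if selection_mode == "global":
        global_keep = select_top_k(chi2_scores(X=X, y=y, n_bins=n_bins), k_features)

    n_repeats = 1 if scheme.kind == "loocv" else scheme.n_repeats
    report = CVReport(
        config={
            "classifier": asdict(clf),
            "scheme": asdict(scheme),
            "k_features": k_features,
            "n_bins": n_bins,
            "selection_mode": selection_mode,
            "n_subjects": tbl.n_subjects,
            "n_features": tbl.n_features,
        }
    )

    for rep in range(n_repeats):
        folds = []
        rep_cm = ConfusionMatrix()
        rep_scores, rep_truth = [], []
        for train_idx, test_idx in _make_splitter(scheme, rep).split(X, y):
            if np.unique(y[train_idx]).size < 2:
                raise ValueError("a training fold contains a single class")
            if selection_mode == "global":
                model = Pipeline(
                    [("scale", StandardScaler()), ("clf", make_classifier(clf))]
                    if clf.standardize
                    else [("clf", make_classifier(clf))]
                )
                model.fit(X[np.ix_(train_idx, global_keep)], y[train_idx])
                X_test = X[np.ix_(test_idx, global_keep)]
                selected = global_keep
            else:
                model = build_pipeline(clf, k_features, n_bins)
                model.fit(X[train_idx], y[train_idx])
                X_test = X[test_idx]
                selected = model.named_steps["select"].selected_
            y_pred = model.predict(X_test)
            scores = _decision_scores(model, X_test)
            cm = ConfusionMatrix.from_predictions(y[test_idx], y_pred)
            rep_cm = rep_cm + cm
            rep_scores.append(scores)
            rep_truth.append(y[test_idx])
            folds.append(
                {
                    "train_idx": np.asarray(train_idx),
                    "test_idx": np.asarray(test_idx),
                    "y_pred": np.asarray(y_pred),
                    "scores": scores,
                    "selected": np.asarray(selected),
                    "confusion": cm,
                }
            )
        metrics = compute_metrics(
            rep_cm, np.concatenate(rep_scores), np.concatenate(rep_truth)
        )
        report.per_repeat.append(
            {"folds": folds, "confusion": rep_cm, "metrics": metrics}
        )

    for name in METRIC_NAMES:
        vals = np.array([r["metrics"][name] for r in report.per_repeat])
        report.summary[name] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return report


def audit_fold_selection(report: CVReport, tbl: FeatureTable) -> dict:
    """Verify that per-fold feature selection used training rows only.

    Recomputes the chi-square top-k from each fold's training rows and
    compares with the selection the fold actually used; also compares
    each fold's selection against the ranking obtained from the full
    table (train + test), which a leaky implementation would have used.

    Returns ``{"per_fold_ok": bool, "n_folds_checked": int,
    "n_folds_differ_from_global": int}`` — the audit passes when
    ``per_fold_ok`` is true, and the last count shows the audit has
    power to detect leakage (folds whose honest selection differs from
    the leaky one).
    """
    k = report.config["k_features"]
    n_bins = report.config["n_bins"]
    X, y = tbl.values, tbl.labels
    global_keep = set(select_top_k(chi2_scores(X=X, y=y, n_bins=n_bins), k).tolist())

    ok = True
    checked = 0
    differ = 0
    for rep in report.per_repeat:
        for fold in rep["folds"]:
            tr = fold["train_idx"]
            expected = select_top_k(
                chi2_scores(X=X[tr], y=y[tr], n_bins=n_bins), k
            )
            used = fold["selected"]
            checked += 1
            if not np.array_equal(np.sort(expected), np.sort(used)):
                ok = False
            if set(used.tolist()) != global_keep:
                differ += 1
    return {
        "per_fold_ok": ok,
        "n_folds_checked": checked,
        "n_folds_differ_from_global": differ,
    }
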