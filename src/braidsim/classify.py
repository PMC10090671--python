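"""Binary classification of deployment success from simulation parameters.

Six classifier families predict whether a parameter combination mu_B leads
to a successful deployment (positive class = success, so sensitivity is
the success-detection rate): logistic regression, k-nearest neighbours,
Gaussian naive Bayes, decision tree, a feed-forward network with three
hidden layers of 10 tanh units, and a support vector machine with a
polynomial kernel of order 2.  Performance is summarised by the confusion
matrix, five scalar metrics (accuracy, sensitivity, specificity,
precision, F1) and the ROC curve with its AUC.

Because a false positive (predicting success for a deployment that would
fail) is the clinically costly error, model selection prefers
high-specificity classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "FittedClassifier",
    "ConfusionMatrix",
    "ClassifierReport",
    "train_classifier",
    "confusion_and_metrics",
    "roc_auc",
    "evaluate_classifiers",
    "select_preferred",
]

FAMILIES = (
    "logistic-regression",
    "k-nearest-neighbour",
    "naive-bayes",
    "decision-tree",
    "feed-forward-network",
    "support-vector-machine",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with its (library-default) hyperparameters."""

    family: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )


def _make_estimator(spec: ClassifierSpec):
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    hp = dict(spec.hyperparameters)
    if spec.family == "logistic-regression":
        return LogisticRegression(**hp)
    if spec.family == "k-nearest-neighbour":
        return KNeighborsClassifier(**hp)
    if spec.family == "naive-bayes":
        return GaussianNB(**hp)
    if spec.family == "decision-tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.family == "feed-forward-network":
        hp.setdefault("hidden_layer_sizes", (10, 10, 10))
        hp.setdefault("activation", "tanh")
        hp.setdefault("max_iter", 4000)
        return MLPClassifier(random_state=spec.seed, **hp)
    # support-vector-machine
    hp.setdefault("kernel", "poly")
    hp.setdefault("degree", 2)
    hp.setdefault("coef0", 1.0)  # inhomogeneous kernel: keep odd-order terms
    return SVC(random_state=spec.seed, **hp)


@dataclass
class FittedClassifier:
    """Fitted model exposing a hard label and a monotone ROC score."""

    spec: ClassifierSpec
    estimator: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=bool)

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X), dtype=float)
        proba = est.predict_proba(X)
        pos = list(est.classes_).index(True)
        return np.asarray(proba[:, pos], dtype=float)


def train_classifier(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec
) -> FittedClassifier:
    """Fit one classifier family on (standardised) predictors.

    Deterministic for a fixed seed.  Raises on single-class training
    labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(spec)
    est.fit(X, y)
    return FittedClassifier(spec=spec, estimator=est)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _ratio(num: float, den: float) -> float:
    """Metric ratio; undefined (NaN) on zero denominator, never 0."""
    return num / den if den > 0 else float("nan")


def confusion_and_metrics(y_true, y_pred):
    """Confusion matrix and the five scalar metrics.

    Positive class is deployment success.  Metrics with zero denominators
    are reported as NaN (undefined), not zero.
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between labels and predictions")
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    cm = ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    metrics = {
        "accuracy": _ratio(tp + tn, cm.total),
        "sensitivity": sensitivity,
        "specificity": _ratio(tn, tn + fp),
        "precision": precision,
        "f1": _ratio(2 * precision * sensitivity, precision + sensitivity),
    }
    return cm, metrics


def roc_auc(y_true, scores):
    """ROC step curve and trapezoid AUC.

    The AUC equals the Mann-Whitney concordance probability (ties counted
    half).  Requires both classes present and finite scores.
    """
    y_true = np.asarray(y_true, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes present")
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class ClassifierReport:
    """Evaluation of one fitted family on a test split."""

    family: str
    confusion: ConfusionMatrix
    metrics: dict
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate_classifiers(
    X_train, y_train, X_test, y_test, seed: int = 0,
    families=FAMILIES, hyperparameters: dict | None = None,
) -> list[ClassifierReport]:
    """Train and evaluate every requested family on one split.

    Predictors should already be standardised with statistics fitted on
    the training split.
    """
    reports = []
    for fam in families:
        hp = (hyperparameters or {}).get(fam, {})
        model = train_classifier(
            X_train, y_train, ClassifierSpec(family=fam, seed=seed,
                                             hyperparameters=hp)
        )
        y_pred = model.predict(X_test)
        cm, metrics = confusion_and_metrics(y_test, y_pred)
        fpr, tpr, auc = roc_auc(y_test, model.score_samples(X_test))
        reports.append(
            ClassifierReport(family=fam, confusion=cm, metrics=metrics,
                             fpr=fpr, tpr=tpr, auc=auc)
        )
    return reports


def select_preferred(reports: list[ClassifierReport]) -> ClassifierReport:
    """Pick the preferred model: highest specificity, ties by accuracy.

    False positives (predicting success for a failing deployment) are the
    clinically costly error, hence the specificity-first utility.
    """
    def key(r: ClassifierReport):
        spec = r.metrics["specificity"]
        acc = r.metrics["accuracy"]
        return (
            -1.0 if np.isnan(spec) else spec,
            -1.0 if np.isnan(acc) else acc,
        )

    return max(reports, key=key)


def metrics_table(reports: list[ClassifierReport]) -> pd.DataFrame:
    """Metrics of all families as a table (one row per family)."""
    rows = []
    for r in reports:
        row = {"model": r.family}
        row.update(r.metrics)
        row["auc"] = r.auc
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
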