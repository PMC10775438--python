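"""Evaluate a feature selection: classification metrics and correlation validity.

Classification quality is reported from per-class one-vs-rest confusion
tables (accuracy, macro precision/recall/F1).  Selection validity is
summarized by mean pairwise feature-feature Pearson correlation (F-F),
mean feature-label correlation (F-L), and their absolute average
O-F = (|F-F| + |F-L|)/2: a selection that keeps mutually coherent,
label-relevant features raises all three.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .datasets import LabeledDataset, SplitSpec, train_test_split
from .fractal import score_all_features
from .selection import apply_selection, select_features

__all__ = [
    "ClassConfusion",
    "EvalReport",
    "CorrelationSummary",
    "confusion_and_metrics",
    "pearson_r",
    "correlation_summary",
    "evaluate_with_classifier",
    "make_classifier",
    "run_grid",
]


@dataclass(frozen=True)
class ClassConfusion:
    """One-vs-rest confusion cells for a single class."""

    label: object
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class EvalReport:
    """Accuracy plus macro-averaged precision/recall/F1 over classes."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: list[ClassConfusion] = field(default_factory=list, repr=False)
    classifier_name: str = ""
    n_features_used: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "classifier": self.classifier_name,
            "n_features_used": self.n_features_used,
        }


@dataclass(frozen=True)
class CorrelationSummary:
    """F-F, F-L and O-F validity summaries of a feature subset."""

    feature_feature: float
    feature_label: float

    @property
    def overall(self) -> float:
        return (abs(self.feature_feature) + abs(self.feature_label)) / 2.0

    def to_dict(self) -> dict:
        return {
            "F-F": self.feature_feature,
            "F-L": self.feature_label,
            "O-F": self.overall,
        }


def confusion_and_metrics(y_true, y_pred, classes=None) -> EvalReport:
    """Tally per-class one-vs-rest confusion tables and macro metrics.

    Accuracy is the fraction of correct predictions.  Precision, recall
    and F1 are computed per class from the one-vs-rest cells and averaged
    unweighted over classes (macro); an undefined ratio (empty
    denominator) counts as 0.  For binary problems the per-class tables
    carry the positive-class values directly.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 1:
        raise ValueError("need at least one prediction")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))

    n = y_true.size
    per_class = []
    for cls in classes:
        t = y_true == cls
        p = y_pred == cls
        tp = int(np.sum(t & p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        per_class.append(ClassConfusion(label=cls, tp=tp, tn=n - tp - fp - fn, fp=fp, fn=fn))

    return EvalReport(
        accuracy=float(np.mean(y_true == y_pred)),
        precision=float(np.mean([c.precision for c in per_class])),
        recall=float(np.mean([c.recall for c in per_class])),
        f1=float(np.mean([c.f1 for c in per_class])),
        per_class=per_class,
    )


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Computed from the centered sum-of-products form.  A constant argument
    makes the coefficient undefined; it is reported as 0 with a warning so
    batch summaries over thousands of features stay total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if den == 0.0:
        warnings.warn("constant input to pearson_r; correlation reported as 0", stacklevel=2)
        return 0.0
    return float(np.clip((dx * dy).sum() / den, -1.0, 1.0))


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    # ordinal integer codes in sorted class order; documented caveat for C > 2
    _, codes = np.unique(labels, return_inverse=True)
    return codes.astype(float)


def correlation_summary(
    dataset: LabeledDataset,
    feature_subset,
    pair_budget: int = 100_000,
    seed: int = 0,
) -> CorrelationSummary:
    """Mean signed F-F and F-L Pearson correlations of a feature subset.

    All feature pairs are enumerated when their number fits the
    ``pair_budget``; otherwise a seeded uniform sample of that many pairs
    is used (all-pairs is quadratic in the subset size).  Labels are
    encoded as integer class codes for the F-L leg.
    """
    subset = np.asarray(list(feature_subset), dtype=int)
    if subset.size == 0:
        raise ValueError("feature subset must be non-empty")
    values = dataset.values[:, subset]
    k = subset.size

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if k < 2:
            ff = 0.0
        else:
            n_pairs = k * (k - 1) // 2
            if n_pairs <= pair_budget:
                ff = float(np.mean([
                    pearson_r(values[:, i], values[:, j])
                    for i, j in itertools.combinations(range(k), 2)
                ]))
            else:
                rng = np.random.default_rng(seed)
                rs = []
                for _ in range(pair_budget):
                    i, j = rng.choice(k, size=2, replace=False)
                    rs.append(pearson_r(values[:, i], values[:, j]))
                ff = float(np.mean(rs))

        codes = _encode_labels(dataset.labels)
        fl = float(np.mean([pearson_r(values[:, j], codes) for j in range(k)]))

    return CorrelationSummary(feature_feature=ff, feature_label=fl)


def evaluate_with_classifier(
    train: LabeledDataset,
    test: LabeledDataset,
    classifier,
    classifier_name: str | None = None,
) -> EvalReport:
    """Fit an injected classifier on train, predict test, report metrics.

    ``classifier`` is any fit/predict estimator (scikit-learn contract).
    Train and test must share the same feature identifiers — the selection
    stage guarantees that when one SelectionResult projects both sides.
    """
    if train.feature_ids != test.feature_ids:
        raise ValueError("train and test feature_ids differ; apply one selection to both")
    classifier.fit(train.values, train.labels)
    y_pred = classifier.predict(test.values)
    report = confusion_and_metrics(test.labels, y_pred, classes=np.unique(train.labels))
    report.classifier_name = classifier_name or type(classifier).__name__
    report.n_features_used = train.n_features
    return report


def make_classifier(name: str, seed: int = 0):
    """Build one of the standard benchmark classifiers by short name.

    nb/dt/rf/svm/knn plus a 'majority' baseline; any stochastic estimator
    is seeded.  Hyperparameters are the library defaults.
    """
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    registry = {
        "nb": lambda: GaussianNB(),
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
        "rf": lambda: RandomForestClassifier(random_state=seed),
        "svm": lambda: SVC(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "majority": lambda: DummyClassifier(strategy="most_frequent"),
    }
    try:
        return registry[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown classifier {name!r}; choose from {sorted(registry)}") from None


def run_grid(
    dataset: LabeledDataset,
    n_blocks_values,
    percent_values,
    classifier,
    seed: int,
    test_fraction: float = 0.3,
) -> pd.DataFrame:
    """Evaluate every (K, p) combination on one fixed train/test split.

    Scores are computed on the training partition only, the selection is
    projected onto both partitions, and a fresh clone of the injected
    classifier is fitted per cell.  Returns one row per combination with
    the metrics and the selected feature count.
    """
    if len(n_blocks_values) == 0 or len(percent_values) == 0:
        raise ValueError("grids must be non-empty")
    train, test = train_test_split(dataset, SplitSpec(seed=seed, test_fraction=test_fraction))
    rows = []
    for k in n_blocks_values:
        scores = score_all_features(train, k)
        for p in percent_values:
            result = select_features(scores, p)
            report = evaluate_with_classifier(
                apply_selection(train, result),
                apply_selection(test, result),
                clone(classifier),
            )
            rows.append(
                {
                    "n_blocks": k,
                    "percent": p,
                    "n_features_used": report.n_features_used,
                    "accuracy": report.accuracy,
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                }
            )
    return pd.DataFrame(rows)
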