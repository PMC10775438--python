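"""Labeled instance-by-feature matrices: loading, normalization, splitting.

The containers here are deliberately thin: a dense numeric matrix with
feature and instance identifiers plus one categorical label per instance.
That is the shape of the gene-expression and image benchmarks this package
targets (tens to hundreds of instances, thousands of features), and it keeps
every downstream stage — fractal scoring, selection, evaluation — a pure
function of arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "DatasetSummary",
    "SplitSpec",
    "read_dataset",
    "write_dataset",
    "min_max_normalize",
    "train_test_split",
    "dataset_complexity",
]


def _round_half_away(x: float) -> int:
    """Round a non-negative real half away from zero."""
    return int(math.floor(x + 0.5))


@dataclass
class LabeledDataset:
    """A dense I x F numeric matrix with per-instance class labels.

    Parameters
    ----------
    values
        Matrix of shape (I, F); float64, no missing values.
    feature_ids
        F feature names, in column order.
    instance_ids
        I instance names, in row order.
    labels
        I class labels (any hashable values).
    """

    values: np.ndarray
    feature_ids: list[str]
    instance_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_inst, n_feat = self.values.shape
        if n_inst < 1 or n_feat < 1:
            raise ValueError("dataset must have at least one instance and one feature")
        if len(self.feature_ids) != n_feat:
            raise ValueError(f"feature_ids has {len(self.feature_ids)} entries, expected {n_feat}")
        if len(self.instance_ids) != n_inst:
            raise ValueError(f"instance_ids has {len(self.instance_ids)} entries, expected {n_inst}")
        if len(self.labels) != n_inst:
            raise ValueError(f"labels has {len(self.labels)} entries, expected {n_inst}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def summary(self) -> "DatasetSummary":
        return DatasetSummary(
            n_classes=self.n_classes,
            n_features=self.n_features,
            n_instances=self.n_instances,
        )

    def subset_instances(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            values=self.values[indices],
            feature_ids=list(self.feature_ids),
            instance_ids=[self.instance_ids[i] for i in indices],
            labels=self.labels[indices],
        )

    def subset_features(self, indices: np.ndarray) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            values=self.values[:, indices],
            feature_ids=[self.feature_ids[i] for i in indices],
            instance_ids=list(self.instance_ids),
            labels=self.labels.copy(),
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Class count C, feature count F, instance count I and complexity O = C*F/I."""

    n_classes: int
    n_features: int
    n_instances: int

    @property
    def complexity(self) -> float:
        return dataset_complexity(self.n_classes, self.n_features, self.n_instances)

    def to_dict(self) -> dict:
        return {
            "C": self.n_classes,
            "F": self.n_features,
            "I": self.n_instances,
            "O": self.complexity,
        }


@dataclass
class SplitSpec:
    """Parameters of a train/test partition.

    ``test_fraction`` of the instances go to the test side, at least one
    instance on each side.  Under ``stratified`` the fraction is applied per
    class (rounded half away from zero), so each class with >= 2 members
    appears in both partitions.  The realized index sets are stored back on
    the spec after :func:`train_test_split` resolves them.
    """

    seed: int
    test_fraction: float = 0.3
    stratified: bool = True
    train_indices: np.ndarray | None = field(default=None, repr=False)
    test_indices: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "test_fraction": float(self.test_fraction),
            "stratified": bool(self.stratified),
            "train_indices": None if self.train_indices is None else [int(i) for i in self.train_indices],
            "test_indices": None if self.test_indices is None else [int(i) for i in self.test_indices],
        }


def dataset_complexity(n_classes: int, n_features: int, n_instances: int) -> float:
    """Complexity index O = C*F/I of a labeled dataset.

    Larger class and feature counts raise the index; more instances lower it.
    High values flag datasets where selection matters most (few samples, many
    features, many classes).
    """
    if n_classes < 1 or n_features < 1 or n_instances < 1:
        raise ValueError("C, F and I must all be positive")
    return n_classes * n_features / n_instances


def read_dataset(
    path: str | Path,
    format: str = "delimited",
    label_column: str | int = "last",
) -> LabeledDataset:
    """Read a labeled matrix from disk.

    ``format="delimited"`` reads CSV/TSV (delimiter inferred from the
    extension, ``.tsv``/``.txt`` -> tab) with a header row; rows are
    instances, columns are features, one column holds the class label.
    ``label_column`` is a column name, a 0-based position, or ``"last"``.

    ``format="benchmark-matrix"`` reads a MATLAB-style container with an
    instance-by-feature matrix ``X`` and integer class codes ``Y``, the
    dialect used by the public high-dimensional selection benchmarks
    (ALLAML, COLON, ...).  Feature order is the stored column order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "benchmark-matrix":
        return _read_benchmark_matrix(path)
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")

    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, header=0)
    if frame.shape[0] < 1 or frame.shape[1] < 2:
        raise ValueError(f"{path}: empty matrix or no feature columns")

    if label_column == "last":
        label_name = frame.columns[-1]
    elif isinstance(label_column, int):
        label_name = frame.columns[label_column]
    else:
        if label_column not in frame.columns:
            raise ValueError(f"{path}: label column {label_column!r} not found in header")
        label_name = label_column

    labels = frame[label_name].to_numpy()
    features = frame.drop(columns=[label_name])
    numeric = features.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~features.isna()
    if bad.to_numpy().any() or features.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        row, col = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: non-numeric or missing value {features.iloc[row, col]!r} "
            f"at row {row}, column {features.columns[col]!r}"
        )
    return LabeledDataset(
        values=numeric.to_numpy(dtype=float),
        feature_ids=[str(c) for c in features.columns],
        instance_ids=[str(i) for i in range(len(frame))],
        labels=labels,
    )


def _read_benchmark_matrix(path: Path) -> LabeledDataset:
    from scipy.io import loadmat

    mat = loadmat(path)
    if "X" not in mat or "Y" not in mat:
        raise ValueError(f"{path}: benchmark matrix must contain 'X' and 'Y'")
    values = np.asarray(mat["X"], dtype=float)
    labels = np.asarray(mat["Y"]).ravel().astype(int)
    return LabeledDataset(
        values=values,
        feature_ids=[f"f{j}" for j in range(values.shape[1])],
        instance_ids=[f"i{i}" for i in range(values.shape[0])],
        labels=labels,
    )


def write_dataset(dataset: LabeledDataset, path: str | Path, label_name: str = "label") -> None:
    """Write a dataset as delimited text (delimiter inferred from extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.DataFrame(dataset.values, columns=dataset.feature_ids)
    frame[label_name] = dataset.labels
    frame.to_csv(path, sep=sep, index=False)


def min_max_normalize(dataset: LabeledDataset) -> LabeledDataset:
    """Rescale each feature independently to [0, 1] by (x - min)/(max - min).

    A constant feature (max == min) maps to all zeros: the transform is
    undefined there and a constant column carries no class information
    either way.  Labels are untouched.
    """
    lo = dataset.values.min(axis=0)
    hi = dataset.values.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    values = (dataset.values - lo) / safe
    values[:, span == 0] = 0.0
    return LabeledDataset(
        values=values,
        feature_ids=list(dataset.feature_ids),
        instance_ids=list(dataset.instance_ids),
        labels=dataset.labels.copy(),
    )


def normalization_params(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (min, max) of a dataset, for fitting the scaler on one partition."""
    return dataset.values.min(axis=0), dataset.values.max(axis=0)


def apply_normalization(dataset: LabeledDataset, lo: np.ndarray, hi: np.ndarray) -> LabeledDataset:
    """Apply a previously fitted min-max transform; constant features map to 0."""
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    values = (dataset.values - lo) / safe
    values[:, span == 0] = 0.0
    return LabeledDataset(
        values=values,
        feature_ids=list(dataset.feature_ids),
        instance_ids=list(dataset.instance_ids),
        labels=dataset.labels.copy(),
    )


def _split_counts(n: int, fraction: float) -> int:
    n_test = _round_half_away(n * fraction)
    return min(max(n_test, 1), n - 1)


def train_test_split(dataset: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition instances into train and test sets.

    Deterministic given ``spec.seed``; the test side gets
    round(I * test_fraction) instances (clipped so both sides are
    non-empty).  Row order within each partition follows the input order.
    Under stratification the fraction is applied class by class, which
    requires every class to have at least two members.
    """
    if not (0 < spec.test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    n = dataset.n_instances
    if n < 2:
        raise ValueError("need at least 2 instances to split")
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        labels = dataset.labels
        test_idx: list[int] = []
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            if len(members) < 2:
                raise ValueError(
                    f"class {cls!r} has a single instance; stratified split impossible "
                    "(use stratified=False)"
                )
            k = _split_counts(len(members), spec.test_fraction)
            test_idx.extend(rng.choice(members, size=k, replace=False))
        test_indices = np.sort(np.asarray(test_idx, dtype=int))
    else:
        k = _split_counts(n, spec.test_fraction)
        test_indices = np.sort(rng.choice(n, size=k, replace=False))

    mask = np.zeros(n, dtype=bool)
    mask[test_indices] = True
    train_indices = np.flatnonzero(~mask)
    spec.train_indices = train_indices
    spec.test_indices = test_indices
    return dataset.subset_instances(train_indices), dataset.subset_instances(test_indices)
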