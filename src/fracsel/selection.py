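"""Rank features by ascending SE and keep the top p percent.

Low SE means high block self-similarity, so the ranking ascends and the
selected set is a prefix of it.  Ties are broken by original feature
index, which makes the whole stage deterministic and platform-stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import LabeledDataset
from .fractal import FeatureScore

__all__ = ["SelectionResult", "count_selected", "select_features", "apply_selection"]


@dataclass
class SelectionResult:
    """Outcome of a top-p% selection over SE-ranked features.

    ``ranking`` is the full permutation of feature indices by ascending
    (SE, index); ``se_values`` is aligned with it.  ``selected_indices``
    are the surviving features, reported in ascending original order so
    column projection preserves the input layout.
    """

    ranking: np.ndarray
    se_values: np.ndarray
    percent: float
    selected_indices: np.ndarray
    n_blocks: int | None = None
    feature_ids: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    def to_dict(self) -> dict:
        return {
            "percent": float(self.percent),
            "n_blocks": self.n_blocks,
            "ranking": [int(i) for i in self.ranking],
            "se_values": [float(v) for v in self.se_values],
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_feature_ids": (
                None
                if self.feature_ids is None
                else [self.feature_ids[i] for i in self.selected_indices]
            ),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "SelectionResult":
        sel = np.asarray(payload["selected_indices"], dtype=int)
        ranking = np.asarray(payload["ranking"], dtype=int)
        ids = payload.get("selected_feature_ids")
        return cls(
            ranking=ranking,
            se_values=np.asarray(payload["se_values"], dtype=float),
            percent=float(payload["percent"]),
            selected_indices=sel,
            n_blocks=payload.get("n_blocks"),
            feature_ids=None if ids is None else list(ids),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def count_selected(n_features: int, percent: float) -> int:
    """Number of features kept at a given percentage.

    max(1, round(F * p / 100)) with half rounded away from zero, so at
    least one feature always survives.  Reproduces the published selected
    counts of the standard benchmarks (e.g. F=2000 at p=21 -> 420,
    F=10304 at p=21 -> 2164).
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not (0 < percent <= 100):
        raise ValueError("percent must lie in (0, 100]")
    return max(1, int(math.floor(n_features * percent / 100.0 + 0.5)))


def select_features(scores, percent: float) -> SelectionResult:
    """Rank by ascending SE (ties by index) and keep the top-p% prefix.

    ``scores`` is a sequence of :class:`~fracsel.fractal.FeatureScore` or a
    bare SE array in feature order.
    """
    if len(scores) == 0:
        raise ValueError("scores must be non-empty")
    if isinstance(scores[0], FeatureScore):
        se = np.array([s.se for s in scores], dtype=float)
        n_blocks = scores[0].n_blocks
    else:
        se = np.asarray(scores, dtype=float)
        n_blocks = None
    if not np.isfinite(se).all():
        bad = int(np.flatnonzero(~np.isfinite(se))[0])
        raise ValueError(f"non-finite SE for feature index {bad}")

    order = np.lexsort((np.arange(len(se)), se))
    k = count_selected(len(se), percent)
    return SelectionResult(
        ranking=order,
        se_values=se[order],
        percent=float(percent),
        selected_indices=np.sort(order[:k]),
        n_blocks=n_blocks,
    )


def apply_selection(dataset: LabeledDataset, result: SelectionResult) -> LabeledDataset:
    """Project a dataset onto the selected features (original column order).

    The same result must be applied to both train and test partitions —
    scoring is never repeated on test data.
    """
    sel = np.asarray(result.selected_indices, dtype=int)
    if sel.min() < 0 or sel.max() >= dataset.n_features:
        raise IndexError(
            f"selected index out of range for a dataset with {dataset.n_features} features"
        )
    return dataset.subset_features(sel)
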