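"""Fractal self-similarity scoring of feature vectors.

Each feature's instance vector is cut into K contiguous range blocks R.
A domain block D is derived from each range by down-sampling (pairwise
averaging, repeated back to block length), and the range is reconstructed
from its own domain by an affine map R ~ S*D + O fitted by least squares.
The root-mean-square residual of that reconstruction measures how
self-similar the block is; summing the per-block RMSE gives the feature's
cumulative score SE.  Features whose values cluster tightly within blocks
(e.g. near-constant per class when instances are grouped by class)
reconstruct almost exactly and score low; unstructured features score high.
Low SE therefore means high self-similarity, and ranking ascends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockPlan",
    "BlockCode",
    "FeatureScore",
    "plan_blocks",
    "decimate_block",
    "fit_scale",
    "fit_offset",
    "block_rmse",
    "feature_se",
    "score_all_features",
]

# Relative threshold below which the scale-fit denominator n*sum(d^2)-(sum d)^2
# is treated as zero (constant domain).
_DEGENERATE_REL_TOL = 1e-12


@dataclass(frozen=True)
class BlockPlan:
    """Partition of a length-``vector_length`` vector into contiguous blocks.

    ``boundaries`` are half-open [start, stop) index pairs covering the
    vector in order.  ``requested_blocks`` is the K asked for;
    ``n_blocks`` is the effective count after the degenerate-input
    adjustment (every block must hold >= 2 points to support a 2-parameter
    affine fit).
    """

    vector_length: int
    requested_blocks: int
    boundaries: tuple[tuple[int, int], ...]

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)

    @property
    def was_adjusted(self) -> bool:
        return self.n_blocks != self.requested_blocks


@dataclass(frozen=True)
class BlockCode:
    """Affine reconstruction parameters and residual for one block."""

    block_index: int
    scale: float
    offset: float
    rmse: float


@dataclass(frozen=True)
class FeatureScore:
    """Cumulative self-similarity score of one feature: SE = sum of block RMSEs."""

    feature_index: int
    se: float
    n_blocks: int


def plan_blocks(vector_length: int, n_blocks: int) -> BlockPlan:
    """Cut ``[0, vector_length)`` into ``n_blocks`` contiguous blocks.

    Base block length is b = floor(vector_length / n_blocks); the first
    K-1 blocks get length b and the remainder is appended to the last
    block.  If b would fall below 2 the effective K is reduced to
    floor(vector_length / 2), reported via ``BlockPlan.was_adjusted``.
    """
    if vector_length < 2:
        raise ValueError("vector_length must be >= 2")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    k = n_blocks
    if vector_length // k < 2:
        k = vector_length // 2
    b = vector_length // k
    bounds = [(j * b, (j + 1) * b) for j in range(k - 1)]
    bounds.append(((k - 1) * b, vector_length))
    return BlockPlan(
        vector_length=vector_length,
        requested_blocks=n_blocks,
        boundaries=tuple(bounds),
    )


def decimate_block(r: np.ndarray) -> np.ndarray:
    """Down-sample a range block into its same-length domain block.

    Adjacent elements are averaged pairwise and each average is written
    twice; an odd trailing element is averaged with itself (kept once).
    The result has the block's length and exactly its mean, so the affine
    fit compares the block with a half-resolution rendering of itself.
    """
    r = np.asarray(r, dtype=float)
    b = r.shape[0]
    if b < 2:
        raise ValueError("block length must be >= 2")
    even = b - (b % 2)
    pairs = r[:even].reshape(-1, 2).mean(axis=1)
    d = np.repeat(pairs, 2)
    if b % 2:
        d = np.append(d, r[-1])
    return d


def _decimate_rows(block: np.ndarray) -> np.ndarray:
    """Column-wise decimation of a (b, F) block; rows are instances."""
    b = block.shape[0]
    even = b - (b % 2)
    pairs = block[:even].reshape(-1, 2, block.shape[1]).mean(axis=1)
    d = np.repeat(pairs, 2, axis=0)
    if b % 2:
        d = np.vstack([d, block[-1:]])
    return d


def fit_scale(d: np.ndarray, r: np.ndarray) -> float:
    """Least-squares slope S of the range on the domain.

    S = (n*sum(d*r) - sum(d)*sum(r)) / (n*sum(d^2) - sum(d)^2); when the
    denominator vanishes (constant domain) S is defined as 0, which hands
    the whole fit to the offset.
    """
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if d.shape != r.shape:
        raise ValueError("domain and range must have equal length")
    n = d.shape[0]
    sd = d.sum()
    den = n * (d * d).sum() - sd * sd
    if den <= _DEGENERATE_REL_TOL * max(1.0, n * (d * d).sum()):
        return 0.0
    return float((n * (d * r).sum() - sd * r.sum()) / den)


def fit_offset(d: np.ndarray, r: np.ndarray, scale: float) -> float:
    """Least-squares intercept O = (sum(r) - S*sum(d)) / n; mean(r) when S = 0."""
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if d.shape != r.shape:
        raise ValueError("domain and range must have equal length")
    n = d.shape[0]
    return float((r.sum() - scale * d.sum()) / n)


def block_rmse(d: np.ndarray, r: np.ndarray, scale: float, offset: float) -> float:
    """Root-mean-square residual of the reconstruction r ~ S*d + O.

    Evaluated in the expanded sum-of-products form
    sqrt((1/n)[sum r^2 + S(S sum d^2 - 2 sum d r + 2 O sum d) + O(n O - 2 sum r)]),
    algebraically identical to the direct residual RMS; the radicand is
    clipped at zero against floating-point cancellation.
    """
    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if d.shape != r.shape:
        raise ValueError("domain and range must have equal length")
    n = d.shape[0]
    inner = (
        (r * r).sum()
        + scale * (scale * (d * d).sum() - 2.0 * (d * r).sum() + 2.0 * offset * d.sum())
        + offset * (n * offset - 2.0 * r.sum())
    )
    return float(np.sqrt(max(inner, 0.0) / n))


def code_block(r: np.ndarray, block_index: int = 0) -> BlockCode:
    """Fit one range block: derive its domain, fit (S, O), measure RMSE."""
    d = decimate_block(r)
    s = fit_scale(d, r)
    o = fit_offset(d, r, s)
    return BlockCode(block_index=block_index, scale=s, offset=o, rmse=block_rmse(d, r, s, o))


def feature_se(x: np.ndarray, n_blocks: int, feature_index: int = 0) -> FeatureScore:
    """Cumulative fractal score of one feature vector.

    Partitions ``x`` per :func:`plan_blocks`, codes each block, and sums
    the per-block RMSEs.  The score is invariant to adding a constant to
    ``x`` and scales linearly with positive multiplication.
    """
    x = np.asarray(x, dtype=float)
    plan = plan_blocks(x.shape[0], n_blocks)
    se = 0.0
    for j, (m1, m2) in enumerate(plan.boundaries):
        se += code_block(x[m1:m2], j).rmse
    return FeatureScore(feature_index=feature_index, se=se, n_blocks=plan.n_blocks)


def score_all_features(dataset, n_blocks: int) -> list[FeatureScore]:
    """Score every feature of a dataset (or raw (I, F) array), in column order.

    Vectorized across features block by block; equivalent to calling
    :func:`feature_se` per column.  Labels are never read — the score is a
    function of the value matrix alone (a filter, not a wrapper).
    """
    values = dataset if isinstance(dataset, np.ndarray) else dataset.values
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected an instance-by-feature matrix")
    n_inst, n_feat = values.shape
    plan = plan_blocks(n_inst, n_blocks)
    se = np.zeros(n_feat)
    for m1, m2 in plan.boundaries:
        block = values[m1:m2]
        dom = _decimate_rows(block)
        n = m2 - m1
        sd = dom.sum(axis=0)
        sr = block.sum(axis=0)
        sdd = (dom * dom).sum(axis=0)
        sdr = (dom * block).sum(axis=0)
        srr = (block * block).sum(axis=0)
        den = n * sdd - sd * sd
        ok = den > _DEGENERATE_REL_TOL * np.maximum(1.0, n * sdd)
        scale = np.where(ok, (n * sdr - sd * sr) / np.where(ok, den, 1.0), 0.0)
        offset = (sr - scale * sd) / n
        inner = srr + scale * (scale * sdd - 2.0 * sdr + 2.0 * offset * sd) + offset * (n * offset - 2.0 * sr)
        se += np.sqrt(np.maximum(inner, 0.0) / n)
    return [FeatureScore(feature_index=j, se=float(se[j]), n_blocks=plan.n_blocks) for j in range(n_feat)]
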