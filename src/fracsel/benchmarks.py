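"""Published characteristics of the ten standard high-dimensional benchmarks.

These are metadata of the public gene-expression and image datasets the
method is usually demonstrated on (the matrices themselves are external
downloads and are never required here): instance/feature/class counts,
the block-count and selection-percentage settings reported as optimal for
each, and the published mean feature-feature (F-F) and feature-label
(F-L) correlation summaries for the full feature set and the selected
subset.  They serve as inputs to the arithmetic this package implements —
complexity indices, selected-feature counts, O-F summaries — not as test
data.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BenchmarkInfo", "BENCHMARKS"]


@dataclass(frozen=True)
class BenchmarkInfo:
    name: str
    n_instances: int
    n_features: int
    n_classes: int
    n_blocks: int          # reported optimal block count
    percent: float         # reported optimal selection percentage
    fullset_ff: float      # mean pairwise feature-feature Pearson r, all features
    fullset_fl: float      # mean feature-label Pearson r, all features
    ffs_ff: float          # same summaries over the selected subset
    ffs_fl: float


BENCHMARKS: tuple[BenchmarkInfo, ...] = (
    BenchmarkInfo("ALLAML", 72, 7129, 2, 2, 16, 0.399, -0.163, 0.681, -0.598),
    BenchmarkInfo("COLON", 62, 2000, 2, 10, 21, 0.382, -0.145, 0.576, -0.470),
    BenchmarkInfo("lung_discrete", 73, 325, 7, 4, 81, 0.122, 0.184, 0.556, 0.419),
    BenchmarkInfo("lung", 203, 3312, 5, 2, 36, 0.360, 0.167, 0.494, 0.324),
    BenchmarkInfo("lymphoma", 72, 7070, 2, 10, 16, 0.281, -0.118, 0.402, 0.317),
    BenchmarkInfo("TOX_171", 171, 5748, 4, 2, 86, 0.119, 0.143, 0.612, 0.547),
    BenchmarkInfo("warpPIE10P", 210, 2420, 10, 10, 6, 0.236, -0.148, 0.454, -0.273),
    BenchmarkInfo("orlraws10P", 100, 10304, 10, 10, 21, 0.185, 0.020, 0.685, 0.486),
    BenchmarkInfo("CLL_SUB_111", 111, 11340, 3, 2, 26, 0.381, 0.259, 0.412, 0.383),
    BenchmarkInfo("GLI_85", 85, 22283, 2, 4, 36, 0.401, 0.182, 0.684, 0.484),
)
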