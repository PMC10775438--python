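# Methods

## Model and procedure

`fracsel` scores each feature of a labeled instance-by-feature matrix by how
well the feature reconstructs itself across scales, borrowing the
range/domain machinery of fractal block coding. The pipeline is:

1. **Normalize.** Each feature is min–max rescaled to [0, 1] independently,
   (x − min)/(max − min) over the feature's own values, so features with
   large raw ranges do not dominate the residuals. A constant feature has a
   zero denominator; it maps to all zeros (it carries no class information
   either way, and this keeps the transform total). The default pipeline
   normalizes the full matrix before splitting; `--fit-normalizer-on-train`
   fits the scaler on training rows only for a leakage-safe variant.
2. **Split.** Stratified 70/30 train/test by default, with a required
   explicit seed. Sizes use round-half-away-from-zero, applied per class
   under stratification; row order within each partition follows the input,
   so contiguous class runs survive the split.
3. **Score.** Each feature's training vector is cut into K contiguous
   blocks: base length b = floor(I/K), first K−1 blocks of length b, the
   remainder appended to the last block. If b would fall below 2, the
   effective K is reduced to floor(I/2) so every block can support a
   2-parameter fit; the adjustment is reported on the `BlockPlan`. Each
   range block R yields a same-length domain block D by pairwise averaging
   with 2× repetition (an odd trailing element is averaged with itself);
   this halves the resolution while preserving the block mean and keeping
   Eqs. for the affine fit well-posed. S and O are the ordinary
   least-squares slope and intercept of R on D, evaluated in closed
   sum-of-products form; when the domain is constant the slope denominator
   vanishes and the limit S = 0, O = mean(R) is used, making the block RMSE
   the population standard deviation of R. The per-block RMSE is evaluated
   in its expanded algebraic form with the radicand clipped at zero against
   floating-point cancellation; the tests verify it equals the direct
   residual RMS to 1e-9. The feature's score SE is the unweighted sum of
   its block RMSEs — consequently SE values are comparable only at a fixed
   K. SE is invariant under adding a constant to the feature and scales
   linearly under positive multiplication; labels are never read (this is a
   filter, not a wrapper).
4. **Select.** Features are ranked by ascending (SE, column index) — low SE
   means high self-similarity — and the top p% survive:
   max(1, round-half-away-from-zero(F·p/100)) features. This rounding is
   the unique simple rule consistent with the published selected counts of
   the ten standard benchmarks (e.g. 10304 features at 21% → 2164). The
   selection is a prefix of the ranking, so selections are nested in p, and
   the one `SelectionResult` fitted on training data projects both
   partitions; scoring is never repeated on test data.
5. **Evaluate.** An injected fit/predict classifier (naive Bayes, decision
   tree, random forest, SVM, k-NN, or a majority baseline; library default
   hyperparameters, seeded where stochastic) is fitted on the projected
   training data and measured on the projected test data. Accuracy is the
   fraction correct; precision, recall and F1 come from per-class
   one-vs-rest confusion tables, macro-averaged, with empty denominators
   counted as 0. Selection validity is summarized by the mean signed
   pairwise feature–feature Pearson r (F-F), the mean feature–label r with
   labels as integer class codes (F-L), and O-F = (|F-F| + |F-L|)/2. For
   subsets with more than 100,000 pairs, F-F uses a seeded uniform sample
   of that many pairs (all-pairs is quadratic). Pearson r with a constant
   argument is undefined; it is reported as 0 with a warning so batch
   summaries stay total. For more than two classes the integer coding of
   labels is ordinal, which understates non-monotone relevance; this is a
   documented caveat rather than a flag-controlled alternative.

The per-dataset complexity index O = C·F/I (classes × features /
instances) summarizes how hard a dataset is: few samples with many features
and classes give large O.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| K (`--blocks`) | contiguous instance blocks per feature | 2 | matches a two-class grouped layout; the published benchmark settings range over 2–10 |
| p (`--percent`) | percentage of features kept | 10 | conservative reduction; published optima range 6–86% |
| test_fraction | held-out share | 0.3 | conventional 70/30 |
| stratified | per-class split | true | tiny class counts otherwise risk empty test classes |
| classifier | evaluation model | rf | strongest of the standard five on these benchmarks |
| pair_budget | max F-F pairs before sampling | 100,000 | keeps the quadratic summary at desk scale, seeded |

All randomness (split, classifier, pair sampling, simulation) flows from
one explicit seed; there is no unseeded randomness anywhere, and repeated
runs are byte-identical.

## Synthetic data: what it emulates and what it does not

The generator produces the regime the method assumes: a minority of
informative features that are near-constant within each class (class means
`class_separation` apart plus Gaussian noise, default sd 0.05) and a
majority of i.i.d. uniform [0, 1] noise features — uniform on the
post-normalization scale so normalization is near-identity on them and SE
differences are attributable to structure, not range. Class sizes differ by
at most one. The reference scenario is 60 instances, 2 classes, 500
features with 25 informative, separation 1.0, noise sd 0.05, instances
grouped by class, seed 7.

It does **not** emulate microarray intensity distributions, batch effects,
feature–feature dependence beyond the shared class means, or label noise.
Passing the recovery and accuracy checks therefore shows the machinery is
correct and that the score separates blockwise-structured from unstructured
features — not that the method wins on any particular real dataset.

**Instance order matters.** Blocks are contiguous instance runs, so SE
depends on how rows are ordered. With instances grouped by class the
informative features are piecewise constant across blocks and score near
zero; shuffling rows mixes classes within blocks and inflates their SE.
This is exposed deliberately: the generator's `instance_order="shuffled"`
mode and `ordering_sensitivity_report` quantify the effect instead of
silently canonicalizing an order. Real data should be sorted by class (or
at least consistently) before scoring.

## Numerical choices

- Ties in SE break by ascending original column index: reproducible across
  runs and platforms.
- The degenerate-domain threshold treats the slope denominator
  n·Σd² − (Σd)² as zero below 1e-12 relative to n·Σd².
- The expanded RMSE radicand is clipped at 0 before the square root.
- Vectors shorter than 2, empty selections, non-finite scores, mismatched
  lengths and single-member classes under stratification are rejected with
  explicit errors rather than propagated as NaN.
- Batch scoring is vectorized across features block by block and agrees
  with the per-feature path to 1e-9 (bit-exactness across different memory
  layouts is not guaranteed, only tolerance-level agreement).

## Known discrepancies and limitations

- The complexity formula C·F/I disagrees with one published benchmark
  table entry (ALLAML: 2·7129/72 = 198.03, printed as 99.014 — exactly
  half, suggesting C was dropped); the formula is implemented uniformly
  with no special case, and one further printed entry (CLL_SUB_111) is off
  by one unit in its last decimal from the exact arithmetic. Tests compare
  to one unit in the last printed place.
- SE sums unweighted block RMSEs, so scores are not comparable across
  different K.
- Reproducing the published per-dataset accuracies requires the ten
  external benchmark matrices and unstated classifier/split settings; the
  harness can run them (`--format benchmark-matrix`) but the package's
  verified surface is the arithmetic above plus the synthetic scenario.
- Problem sizes in the test suite (up to 60×500 matrices, 200-seed null
  calibration at 20×100) were chosen as desk-scale defaults that exercise
  every code path.
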