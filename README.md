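# fracsel — fractal feature selection for high-dimensional labeled data

High-dimensional biological matrices — gene-expression profiles with
thousands of probes and a few dozen samples, image pixel matrices — swamp
classifiers with noisy, irrelevant columns. `fracsel` implements a filter
feature-selection method based on fractal self-similarity: it scores each
feature without consulting any classifier, ranks features by the score, and
keeps the most self-similar ones.

## The method

For one feature, take its instance vector **x** (length *I*), cut it into
*K* contiguous **range blocks** *R*. From each range derive a **domain
block** *D* by down-sampling (adjacent pairs averaged, each average written
twice), and reconstruct the range from its own domain with an affine map

&nbsp;&nbsp;&nbsp;&nbsp;*R* ≈ *S·D* + *O*

where the scale *S* and offset *O* are the least-squares slope and intercept
of the range on the domain. The per-block root-mean-square residual

&nbsp;&nbsp;&nbsp;&nbsp;RMSE = √( (1/n) Σᵢ (rᵢ − S·dᵢ − O)² )

measures how self-similar the block is; the feature's score is the
cumulative error SE = Σ over blocks of RMSE. Features whose values cluster
tightly within blocks — in particular features that are nearly constant
within each class when instances are grouped by class — reconstruct almost
exactly and get **low SE**. The selection keeps the top *p*% of features by
ascending SE (ties broken by column index), projects train and test data
onto that one set, and evaluates it with standard classification metrics
(accuracy, macro precision/recall/F1) and correlation summaries: mean
pairwise feature–feature Pearson *r* (F-F), mean feature–label *r* (F-L),
and O-F = (|F-F| + |F-L|)/2.

Also included: a complexity index O = C·F/I per dataset (classes × features
/ instances), a synthetic-data generator with ground-truth informative
features so the whole pipeline is testable without downloads, and loaders
for CSV/TSV plus the MATLAB-style dialect of the public selection
benchmarks (ALLAML, COLON, …).

## Worked example

Simulate a 60×500 two-class matrix in which 25 features carry the class
signal (class means 1.0 apart, noise sd 0.05) and the rest are uniform
noise, then run the full pipeline — normalize, stratified 70/30 split,
score with K=2 blocks on the training rows, keep the best 10%, fit a seeded
random forest:

```bash
fracsel simulate -i 60 -f 500 -c 2 -m 25 --seed 7 --output demo.csv --truth truth.json
fracsel run --input demo.csv --seed 7 -k 2 -p 10 --output-dir demo_run
cat demo_run/report.json
```

```json
{
 "accuracy": 1.0,
 "precision": 1.0,
 "recall": 1.0,
 "f1": 1.0,
 "classifier": "rf",
 "n_features_used": 50,
 "correlation": {
  "F-F": 0.24292907735742944,
  "F-L": 0.49320096014143355,
  "O-F": 0.3680650187494315
 }
}
```

The 50 surviving features (10% of 500) include all 25 informative ones, so
the classifier is perfect on the 18 held-out instances. The correlation
block shows why the selection is valid: the selected subset's O-F is 0.368,
whereas the same summary over all 500 features (`fracsel
validate-correlation --input demo.csv`) is 0.027 — the kept features are
mutually coherent and label-relevant, the discarded ones are not.
`demo_run/` also contains `scores.tsv` (per-feature SE and rank),
`selection.json` (the full ascending-SE ranking and the kept set) and the
projected train/test matrices.

Other subcommands: `score`, `select`, `transform`, `evaluate`,
`validate-correlation`, `grid` (evaluate a K × p grid), each a thin wrapper
over the library functions in `fracsel.*`.

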