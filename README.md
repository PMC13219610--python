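# toxqsar

Constraint-aware, uncertainty-informed QSAR modelling of *Tetrahymena
pyriformis* toxicity (pIGC50) from eight physicochemical descriptors
(NRB, nROH, nDB, MW, A, LogP, GATS1p, B).

The toolkit implements, from first principles on the scientific Python stack:

- **PC-GBM** (`toxqsar.gbm`) — gradient-boosted regression trees with
  per-feature monotonicity constraints enforced during split search via
  bound-interval propagation (LogP, MW, nDB non-decreasing; nROH
  non-increasing), exact greedy splits, L1/L2 leaf regularization, gain
  importances, and an independent monotonicity auditor.
- **Variational BNN** (`toxqsar.bnn`) — mean-field Bayes-by-backprop MLP
  (32, 16 hidden units, ReLU, 1/fan-in Gaussian priors, learned
  homoscedastic noise) producing predictive means, SDs, and central
  intervals.
- **Symbolic regression** (`toxqsar.symreg`) — genetic programming over
  {+, −, ×, protected ÷} with parsimony pressure, linear scaling, memetic
  constant refits, and depth/node caps.
- **Ensemble** (`toxqsar.ensemble`) — inverse-CV-RMSE weighted Gaussian
  mixture of PC-GBM and BNN predictions.
- **Metrics** (`toxqsar.metrics`) — RMSE, R², MARE, MAE, mean interval
  width, Theil inequality coefficient, coverage/calibration error/sharpness/
  NLL, folded standardized-residual diagnostics, through-origin external
  validation slopes (k, k′, R₀²), and CV-residual conformal intervals for
  point models.
- **Validation** (`toxqsar.validation`) — Y-scrambling with out-of-sample
  scoring, centroid-distance applicability domain, and
  uncertainty–distance/error association analysis.
- **Sensitivity** (`toxqsar.sensitivity`) — one-at-a-time descriptor sweeps
  over observed ranges with directional classification and a
  monotonic-consistency percentage.
- **Tuning** (`toxqsar.tuning`) — seeded GP-surrogate/expected-improvement
  search over bounded hyperparameter spaces minimizing the composite loss
  `RMSE + λ₁·max(0, nominal − coverage) + λ₂·PI`.
- **Synthetic data** (`toxqsar.synthetic`) — a calibrated generator whose
  marginals match the reference descriptor distribution table (truncated
  normal / truncated lognormal / mode-matched binomial families) and whose
  response surface embeds a planted affine form
  `0.42·LogP + 0.015·MW − 0.31·GATS1p + 0.05·nDB − 0.05·nROH + C + ε`,
  with the intercept and noise SD solved by post-clipping moment matching
  (target mean 3.267, SD 1.051).
- **Partitioning** (`toxqsar.partition`) — PCA → k-means cluster-aware
  80/20 splitting with exact-count rebalancing (1792 → 1434/358), balanced
  k-fold CV plans, and label permutation for Y-scrambling.
- **Pipeline + CLI** (`toxqsar.pipeline`, `toxqsar.cli`) — end-to-end
  orchestration with leakage discipline, JSON report bundling, and
  reproducible per-stage sub-seeding.

## Tests

```bash
python -m pytest -q tests/
```

The suite (~240 tests, ≈3 min on one CPU) includes unit tests per module,
hypothesis/property tests for the metric invariants, and
`tests/test_acceptance.py`, which implements the acceptance criteria
(split counts, generator moment recovery, metric-definition reproduction,
brute-force oracle equivalence, monotonicity audits, model recovery bands,
Y-scrambling collapse, and the sensitivity worked example).

## CLI

```bash
toxqsar generate --n 1792 --seed 1 --out compounds.csv
toxqsar summarize compounds.csv
toxqsar preprocess compounds.csv --k-select 8
toxqsar split compounds.csv --frac 0.2 --out plan.json
toxqsar sensitize compounds.csv --anchors 200
toxqsar run-all --seed 7 --out-dir runs/demo       # full pipeline
```

`run-all` writes `report.json` (per-model train/CV/test metrics, fold table,
Y-scrambling, applicability domain, sensitivity, importances, provenance),
`predictions_<model>.csv`, and aligned text/CSV tables under `tables/`.

Input CSVs are comma-separated UTF-8 with a mandatory header, first column
`compound_id`, one numeric column per descriptor, and an optional `pIGC50`
target column.

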