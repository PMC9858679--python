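# genechain

A toolkit for multi-label multi-class genetic-disorder prediction on
clinical-genomic tabular data. Each patient carries two categorical labels —
a 3-class disorder type and a 9-class disorder subclass — and the package
provides the full modelling stack:

- **`genechain.schema`** — the 44-column patient-table schema (exact header
  strings, category alphabets, per-column reference null counts) and
  CSV I/O with explicit null semantics (empty cell = null).
- **`genechain.preprocess`** — the fixed 13-column drop list, the integer
  encoding maps (code alphabet {−1, 0, 1, 2}, e.g. Yes/No → 1/0,
  'Not applicable' → −1, 'Ambiguous' → 2), zero-fill of remaining nulls,
  disorder-class undersampling, and seeded (optionally stratified)
  train/test splitting.
- **`genechain.etrf`** — hybrid class-probability feature stacking: an
  extra-trees and a random-forest model are fitted per target and their
  predicted class probabilities concatenated into a 24-wide feature set
  (block order ET-disorder, ET-subclass, RF-disorder, RF-subclass).
  Training-row features are out-of-fold by default (leak-free stacking);
  an in-sample mode is available.
- **`genechain.chain`** — a from-scratch classifier chain over the 12
  binarized label classes (true-label conditioning at fit time, predicted
  conditioning at inference, argmax-per-block decoding), plus independent
  per-label baselines, a 2-stage categorical chain variant, and a registry
  of eight configured learners (LR, MLP, DTC, RFC, KNN, ETC, XGB, SVC).
- **`genechain.metrics`** — Hamming loss, example-based row-Jaccard
  accuracy, label-based macro accuracy, the generalized-Jaccard
  alpha-evaluation score `(1 − (β·FN + γ·FP)/|union|)^α`, and per-label
  precision/recall/F1 reports.
- **`genechain.synthetic`** — a schema-faithful synthetic patient
  generator with configurable class priors, per-column missingness (a
  ready-made profile mirrors the reference dataset's null rates), a
  planted disorder→subclass hierarchy, and four feature–label scenarios
  (`separable`, `noisy_linear`, `nonlinear_interaction`,
  `independent_labels`).
- **`genechain.experiment`** — seeded experiment grids over
  learners × split ratios × {raw, hybrid} features × {imbalanced,
  balanced} data, with per-arm JSON reports and a combined tidy CSV.

Note: the `XGB` registry entry is backed by scikit-learn's
`HistGradientBoostingClassifier` (the xgboost package is not part of the
runtime environment).

## CLI

```sh
# generate a synthetic cohort + ground-truth sidecar
genechain simulate --scenario noisy_linear --n 2000 --seed 7 --out data/

# encode (and optionally balance) a patient CSV
genechain preprocess --data data/data.csv --out encoded/ --seed 7 --balance

# train a chain on hybrid features and write a report
genechain train --data data/data.csv --learner RFC --feature-mode etrf \
    --split 0.8 --seed 7 --out model/

# evaluate label-pair predictions against truth
genechain evaluate --truth model/truth.csv --pred model/predictions.csv \
    --out report.json

# run a full grid from a YAML config
genechain experiment --config grid.yaml --seed 7 --out runs/
```

Example `grid.yaml`:

```yaml
data: {n_rows: 2000, scenario: noisy_linear, seed: 1}
learners: [LR, DTC, RFC, XGB]
split_fractions: [0.7, 0.8, 0.85, 0.9]
feature_modes: [raw, etrf]
balance_modes: [imbalanced, balanced]
```

Exit codes: 0 success, 2 configuration error, 3 data error.

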