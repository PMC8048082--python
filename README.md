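# mtqsarx

Multitarget (mt-)QSAR classification for datasets whose rows are
(compound × experimental condition) data points. The library converts
externally computed molecular descriptors into **condition-dependent
deviation descriptors** via four moving-average operators, builds linear
discriminant models with two deterministic feature selectors, tunes six
non-linear classifiers by exhaustive grid search, and provides the
validation machinery around them: a leakage-safe three-set design,
response+condition randomisation, applicability-domain estimation, and
condition-wise prediction reports.

## What it does

1. **Dataset I/O** (`mtqsarx.dataset`) — CSV datasets with a YAML
   column-role schema: case id, binary response (+1/−1), one or more
   categorical condition columns, numeric descriptors, optional
   "Train"/"Test" tags and per-row probability factors. A synthetic
   generator plants per-(condition element, descriptor) mean shifts and a
   class effect so deviation descriptors carry a known signal.
2. **Splitting** (`mtqsarx.splitting`) — training/validation division by
   pre-defined tags, seeded random draw, or k-means cluster analysis
   (z-scored descriptors, per-cluster sampling), followed by a
   sub-training/test (calibration) sub-division. Fractional counts round
   half up.
3. **Deviation descriptors** (`mtqsarx.boxjenkins`) — Methods 1–4:
   difference from the element's active mean, optionally normalised by
   the training descriptor range, the element's active fraction, or a
   per-row probability factor (user supplied, or composed from
   primary/secondary element count ratios). All statistics are fitted on
   the training set only.
4. **Linear modelling** (`mtqsarx.linear`) — variance/correlation
   pre-treatment; forward stepwise selection on OLS p-values (p-to-enter /
   p-to-remove) and cross-validated sequential forward (floating)
   selection scored by accuracy or AUROC; Wilks' λ, F and p on the
   discriminant scores; cross-correlation matrix; randomisation of the
   response *and* condition columns with full re-derivation of the
   deviation statistics per run.
5. **Non-linear modelling** (`mtqsarx.nonlinear`) — kNN, Bernoulli NB,
   SVC, random forest, gradient boosting and MLP with grid-searched or
   user-specified hyperparameters (default grids ship as CSV in
   `mtqsarx/grids/`), plus a confidence-threshold applicability domain.
6. **Evaluation** (`mtqsarx.evaluation`) — confusion-matrix metric block
   (sensitivity, specificity, accuracy, F1, MCC), ROC/AUROC, the
   standardisation-rule applicability domain for linear models, and
   per-condition-tuple accuracy reports with "na" cells for absent tuples.

## CLI walkthrough

```sh
# synthetic dataset + schema
mtqsarx synth --n-rows 400 --n-descriptors 5 --cardinalities 3,2 \
    --effect-size 1.5 --seed 1 --out data.csv --schema-out schema.yaml

# three-set assignment (random / predefined / kmca)
mtqsarx split --data data.csv --schema schema.yaml --scheme random \
    --val-fraction 0.25 --test-fraction 0.2 --seed 2 --out assignment.csv

# deviation descriptors (Method 1-4), per-set feature files + audit bundle
mtqsarx transform --data data.csv --schema schema.yaml \
    --assignment assignment.csv --method 1 --out-dir features/

# linear model (fs or sfs selector)
mtqsarx lda --features-dir features/ --selector fs --p-enter 0.05 \
    --p-remove 0.05 --max-desc 10 --corr-cut 0.999 --var-cut 0.001 \
    --out model.csv

# diagnostics
mtqsarx evaluate --features-dir features/ --model model.csv \
    --out report.csv --roc-out roc.csv --roc-plot roc.png
mtqsarx ycr --data data.csv --schema schema.yaml --assignment assignment.csv \
    --model model.csv --runs 100 --seed 0 --out ycr.csv
mtqsarx ad  --features-dir features/ --model model.csv --out ad.csv
mtqsarx cwp --features-dir features/ --model model.csv --data data.csv \
    --schema schema.yaml --assignment assignment.csv --out cwp.csv

# non-linear model with a hyperparameter grid
mtqsarx ml --features-dir features/ --mode grid --learner rf \
    --folds 5 --seed 1 --ad-threshold 0.7 --out ml.csv
```

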