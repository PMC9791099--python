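# vocims

Cross-validated classification of GC-IMS (gas chromatography – ion mobility
spectrometry) urinary VOC chromatograms, with a fully synthetic,
ground-truthed cohort generator so every stage of the pipeline is testable
without instrument data.

The pipeline reproduces a common clinical-metabolomics analysis design:

1. **Simulate** (`vocims.synthetic`) — retention-time × drift-time intensity
   grids built from Gaussian analyte peaks, a reactant-ion ridge, baseline
   drift and truncated Gaussian noise; class structure is planted by scaling
   selected peak amplitudes, and a ground-truth sidecar records the pixel
   footprint of every discriminative peak. Sample manifests carry clinical
   covariates (gestational-age categories, infection flags, CRP, cervical
   length) with consistent invariants.
2. **Preprocess** (`vocims.preprocess`) — crop a central window, zero all
   intensities strictly below a shared threshold (calibrated so the median
   sample keeps ~10,000 non-zero pixels), and flatten row-major with a
   recoverable pixel ↔ (rt, dt) mapping.
3. **Select & classify** (`vocims.selection`, `vocims.crossval`) —
   stratified 10-fold cross-validation; *within each fold* features are
   ranked by two-sided Wilcoxon rank-sum p-values on the training rows only,
   the 100 smallest are kept, and L1-logistic regression, a Platt-calibrated
   linear SVM, and an RBF Gaussian-process classifier produce pooled
   out-of-fold class probabilities. A deliberately leaky variant
   (`run_cv_global_selection`) exists solely to demonstrate selection
   leakage on null data.
4. **Evaluate** (`vocims.evaluate`) — Mann–Whitney AUC with DeLong 95% CI,
   rank-sum class-separation p-value, Youden-optimal operating point,
   sensitivity/specificity with Clopper–Pearson CIs, PPV/NPV, and
   best-classifier selection by AUC (ties: smaller p, fixed name order).
5. **Baseline stats** (`vocims.cohort_stats`) — Table-1 style group
   comparisons: one-way ANOVA for continuous variables; Pearson chi-squared
   or (for 2×2 tables with an expected cell < 5) a point-probability
   two-sided Fisher exact test for categorical ones.
6. **Orchestrate** (`vocims.pipeline`, `vocims.cli`) — comparisons are
   manifest query predicates (e.g. `who_group == '2'` vs `who_group ==
   '4b'`, `chorioamnionitis` vs `~chorioamnionitis`), so merged subgroups
   are configuration, not code. Runs are deterministic given the config
   seed.

## CLI

```sh
vocims simulate --out ws --seed 1 --n-term 26 --n-preterm 52
vocims preprocess --workspace ws --out features --target-nnz 10000
vocims run --workspace ws --config run.yaml --out results
vocims report --bundle results/report.json --out results/table.csv
```

Example `run.yaml`:

```yaml
n_folds: 10
k: 100
seed: 1
target_nnz: 10000
comparisons:
  - name: preterm_vs_term
    predicate_a: delivery_class == 'term'
    predicate_b: delivery_class == 'preterm'
  - name: chorioamnionitis
    predicate_a: ~chorioamnionitis
    predicate_b: chorioamnionitis
```

The run emits `report.json` (full per-classifier results, per-fold selected
features, config hash) plus `comparisons.csv` and `baseline.csv`.

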