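# plaqomics

Integrative multi-omics classification of hemorrhaged atherosclerotic
plaques: multiblock sparse PLS discriminant analysis with stability-based
signature selection, plus the preprocessing, tuning, validation and
enrichment statistics around it.

## The problem

Intraplaque hemorrhage (IPH) marks a carotid plaque as high-risk, but no
single molecular layer explains it well. Given transcriptomic, proteomic and
peptidomic profiles of the same plaque segments (a small two-group cohort,
e.g. 16 non-IPH vs 26 IPH samples), the task is to (i) build a classifier
that separates IPH from non-IPH plaques using all three layers jointly,
(ii) extract a compact, reproducible gene signature driving that separation,
and (iii) characterise the signature downstream (differential expression,
component–trait correlations, gene-set overrepresentation, preranked GSEA,
validation on independent cohorts).

This package implements that workflow end-to-end and ships a synthetic-data
generator with planted ground truth, so every stage can be exercised and
scored without access to the original cohorts.

## The model

Each omics block X_b (samples × features, scaled to zero mean / unit
variance per feature) is projected onto latent components t_b = X_b a_b.
The outcome enters as a centered class-indicator block Y. Loadings are
estimated by cyclically maximising the design-weighted sum of covariances

    Σ_{b,j} C[b,j] · cov(X_b a_b, X_j a_j) + Σ_b C[b,outcome] · cov(X_b a_b, Y b_Y)

where C is a symmetric design matrix (by default 0.1 between omics blocks
and 1.0 between each block and the outcome). Sparsity is enforced by
soft-thresholding each loading update to a per-block budget keepX, so every
component names exactly keepX features per block. After each component the
X blocks are deflated by regression on their own scores, which makes
within-block component scores exactly orthogonal.

Around this core:

- **Preprocessing** — features with ≥ 50 % missing values are discarded,
  the rest imputed by unsupervised sample-wise k-NN (k = 7); the complete
  transcriptomics block is reduced to its most variable features.
- **Tuning** — keepX and the component count are selected by stratified
  5-fold cross-validation (repeated, seeded) scored with the balanced error
  rate; the canonical candidate grids enumerate to 26 (single-omics) and
  14 (integrative) budgets per component.
- **Stability selection** — the tuned model is refitted on stratified 80 %
  resamples drawn with replacement; each feature accumulates |loading|
  across copies, and the top-keepX features per block/component are unified
  to gene symbols and deduplicated into the final signature.
- **Downstream** — per-feature log2FC with paired/Welch t-tests (BH
  adjusted; positive log2FC = higher in IPH), Pearson component–trait
  correlations with p-values, hypergeometric overrepresentation against GMT
  gene sets, a cofactor-target hypergeometric test, preranked GSEA, and
  signature validation with logistic regression / RBF-SVM / decision trees
  under repeated stratified CV.

## Worked example

```python
from plaqomics import (SimulationConfig, generate_multiomics, make_design,
                       MultiblockSPLSDA, ModelSpec, stratified_kfold_cv,
                       ResamplePlan, stability_select, finalize_signature)
from plaqomics.preprocess import preprocess_dataset, PreprocessParams

cfg = SimulationConfig(
    n_per_class=(16, 26),
    block_specs=[("gene", 1000, 0.0), ("protein", 300, 0.2645), ("peptide", 400, 0.3894)],
    n_informative=10, effect_size=2.0, seed=1,
)
data, truth = generate_multiomics(cfg)
data, report = preprocess_dataset(data, PreprocessParams(top_n_variance=None))

model = MultiblockSPLSDA(data, make_design(data.block_names), ncomp=1, keep_x=10)
results = model.fit()
print(results.summary())

spec = ModelSpec(kind="multiblock", ncomp=1, keep_x=10,
                 design=make_design(data.block_names))
print(stratified_kfold_cv(data, spec, n_repeats=50, seed=2).summary())

imp = stability_select(data, spec, ResamplePlan(n_copies=200, base_seed=3))
sig = finalize_signature(imp, {b: [10] for b in data.block_names},
                         truth.symbol_map, name="MULTI 1")
print(len(sig), "signature symbols")
```

prints

```
Multiblock sparse PLS-DA results
================================================
samples: 42   blocks: gene(1000), protein(300), peptide(349)
classes: ['IPH', 'nonIPH'] (positive: IPH)
components: 1
  gene: keepX=[10] selected=[10]
  protein: keepX=[10] selected=[10]
  peptide: keepX=[10] selected=[10]
component-phenotype correlation: comp1=0.827
accuracy 0.905 +- 0.089, AUC 0.972 +- 0.047 (5-fold CV, 50 repeats)
21 signature symbols
```

The peptide block shrinks from 400 to 349 features (the ≥ 50 % missingness
filter), the integrative model selects exactly 10 features per block on one
component, cross-validated accuracy ≈ 0.90 and AUC ≈ 0.97 reflect the
planted effect size of 2 within-class SDs, and the 30 selected features
collapse to 21 unique gene symbols because planted features share symbols
across blocks.

The same run is available from the shell:

```bash
plaqomics run-all --config config.yaml --outdir run/
```

with subcommands `simulate`, `preprocess`, `tune`, `fit`, `select`,
`diffexp`, `enrich`, `validate` for the individual stages. Every stage is
seeded; re-running a config reproduces byte-identical outputs.

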