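# Methods

This note documents the models and procedures implemented in `plaqomics`,
their assumptions, the defaults that matter, and the design choices made
where the design was genuinely open.

## Sparse PLS discriminant analysis

**Single block.** The feature matrix X (samples × features) is scaled per
feature to zero mean and unit variance (SD with one delta degree of
freedom; constant features are mapped to zero rather than dividing by
zero). The binary outcome is coded as a centered one-column-per-class
indicator matrix Y. For each component the algorithm alternates

1. outcome weights b ∝ Yᵀt (unit norm) and outcome score u = Yb,
2. block loading a = soft_select(Xᵀu, keepX) and block score t = Xa,

until the largest loading change falls below `tol` (default 1e-6, at most
100 sweeps; exceeding the limit raises a `ConvergenceError` carrying the
last iterate). Initialisation is the dominant left singular vector of the
cross-covariance XᵀY — deterministic, no random start. With keepX covering
all features and one component, the fixed point is the dominant right
singular vector of YᵀX; the test suite verifies this against a direct SVD.

**Soft selection.** `soft_select(v, keep)` subtracts the (keep+1)-th
largest |v| from every surviving magnitude (sign preserved) and rescales to
unit norm, yielding exactly `keep` nonzeros when magnitudes are distinct.
Ties at the threshold are broken toward the lower feature index; in the
fully tied degenerate case the top-`keep` entries are kept at their raw
values. The largest-magnitude entry of every final loading is made
positive, so fitted models are sign-deterministic.

**Multiblock.** Blocks are coupled through a symmetric design matrix C over
blocks ∪ {outcome} with zero diagonal and entries in [0, 1]; the default
(`make_design`) uses 0.1 between omics blocks and 1.0 from every block to
the outcome. Per component, block loadings are updated cyclically: the
update direction for block b is Σ_j C[b,j]·X_bᵀt_j over connected blocks
plus C[b,outcome]·X_bᵀu, thresholded at keepX_b. The outcome score u is
recomputed after every sweep from the design-weighted sum of block scores.

**Deflation.** Each X block is deflated by regression on its own score
(X ← X − t pᵀ with p = Xᵀt/tᵀt), which makes within-block scores of
different components orthogonal by construction (verified to 1e-8). The
outcome block is *not* deflated: for a binary outcome the centered
indicator matrix has rank one, so regressing it on its own score would
annihilate it after the first component and leave nothing to supervise
later components. Keeping Y fixed preserves supervision for every
component while X-deflation alone guarantees score orthogonality. With
zero inter-omics design weights this multiblock update reduces exactly to
independent single-block fits (the outcome score direction is fixed by the
rank-one indicator), an identity the suite checks to 1e-6 against the
separate single-block implementation.

**Prediction.** New samples are scaled with the stored training parameters
and projected component-by-component with the stored regression loadings.
Each block produces predicted indicator values Ŷ_b = T_b C_bᵀ + ȳ; the
per-block class call is the argmax ("max.dist" — the simplest rule
consistent with reporting AUC from a continuous score), and the aggregated
score is the design-weighted average of the per-block indicator
predictions. The continuous score used for AUC is the aggregated indicator
value of the positive class. The published account does not state a
prediction distance; max.dist on indicator predictions is this package's
documented contract.

## Preprocessing

- **Missingness filter**: features missing in ≥ 50 % of samples are
  discarded (the comparison is `≥`, so a feature missing in exactly half
  the samples is dropped). Idempotent; returns the discarded ids.
- **k-NN imputation** (default k = 7): sample-wise and unsupervised.
  Distances between samples are Euclidean over mutually observed features,
  scaled by the number of such features — without that scaling distances
  collapse under 26–39 % missingness. A missing value becomes the
  unweighted mean of the feature's observed values among the k nearest
  neighbours; if none of them observed the feature, the feature's overall
  observed mean is used and a warning logged. Observed entries are never
  modified.
- **Normalization stand-ins**: the platform-specific procedures of the
  original pipelines (array variance stabilization + robust spline
  normalization; reference-gene scaling of MS ratios) need raw platform
  data, so two intent-preserving stand-ins are provided: `log_median`
  (log2, then per-sample median centering) and `reference_geomean`
  (per-sample division by the geometric mean of the complete-case
  features, then log2; invariant to per-sample scale factors). Missing
  entries stay missing through normalization.
- **Variance filter**: the complete transcriptomics block keeps its
  `top_n_variance` most variable features (10,000 at study scale); ties
  break lexicographically by feature id.
- Order of operations: normalize → missingness filter → impute for the
  MS blocks; normalize → variance filter for the complete block.

Whether the original imputation used samples or features as neighbours is
not documented; sample-neighbour imputation is implemented because with
features ≫ samples it is the better-conditioned direction, and it is what
"unsupervised" most naturally means here (no labels consulted either way).

## Tuning and performance estimation

Model selection scores candidates with the **balanced error rate** (mean of
per-class error rates), which does not reward majority-class guessing in
the unbalanced 16 vs 26 design. CV is stratified k-fold (default 5) with
shuffled folds; repeat r uses derived seed `base + r`. All fold-level
fitting — including feature scaling — happens on the training portion
only; a dedicated test plants a full-data feature screen and confirms the
honest CV does not show the inflated AUC.

keepX is tuned sequentially per component (earlier components frozen, all
candidate combinations for the current component scanned), matching common
practice for these grids and keeping the search tractable; ties prefer the
smaller total budget, then the lexicographically smaller combination, then
the smaller component count. The canonical candidate grids are inclusive
piecewise ranges: 3–30 by 3, 30–60 by 6, 60–150 by 15, 150–300 by 30
(26 distinct values, single-omics) and 10–50 by 5, 50–100 by 10 (14
distinct values, integrative).

AUC is the exact rank statistic P(score_pos > score_neg) + ½P(tie),
computed from rank sums. Default repeat counts are desk-scale (tens);
study-scale counts (1,000–10,000) are supported but not default.

A caveat worth knowing: at strong separation (planted effect size 2) the
balanced error rate for any budget covering the planted features is
near-tied, so the tuner reliably avoids under-covering budgets but may
land on a larger near-equivalent one after CV noise.

Patient pairing is *not* respected in fold construction (matching the
workflow this package reimplements); paired samples of one patient can
land in train and test folds of the same split, which can make CV
estimates slightly optimistic on paired cohorts.

## Stability selection and the signature

Each resample copy draws, per class, round(0.8 · n_class) samples *with
replacement* (round-half-up: 16 and 26 samples give 13 + 21 draws), so the
phenotype distribution matches the cohort. The tuned model is refitted on
every copy (copy i uses seed base + i); each (block, component, feature)
accumulates the absolute loading weight — absolute, because loading signs
can flip between fits — and the selection frequency. Copies that fail to
fit are skipped and counted; more than 10 % failures aborts. The default
copy count is 200 (study scale: 10,000).

The signature takes the top keepX features per (block, component) by
aggregate importance, maps identifiers to gene symbols, and keeps one row
per symbol: the maximum-importance occurrence, which also fixes the
symbol's component assignment; the provenance column lists every
contributing block. Rows are ordered by descending importance.

## Downstream statistics

- **Differential expression**: per-feature log2FC = mean(IPH) −
  mean(non-IPH) on log2 data (positive ⇒ higher in IPH). The test is a
  paired t-test when the patient pairing covers every sample with exactly
  one sample per group, otherwise Welch's t-test; BH adjustment across
  features. Empirical-Bayes variance moderation is deliberately not
  implemented — on the synthetic acceptance surface the ordinary
  linear-model t is the documented choice, and its null type-I rate is
  verified at 5 %. Zero-variance features get p = 1 and a `degenerate`
  flag.
- **Correlations**: Pearson r with the two-sided p from
  t = r√((n−2)/(1−r²)) on n−2 df.
- **Overrepresentation**: upper-tail hypergeometric P(X ≥ k) per gene set
  (verified against exhaustive enumeration for small universes), BH across
  sets, against an explicit background universe; sets are restricted to
  the universe first. The cofactor-target test is the same statistic
  reported side by side per cofactor set; its p-value is sensitive to the
  universe choice, which is therefore an explicit argument.
- **Preranked GSEA**: list sorted by decreasing statistic; hits advance
  the running sum by |stat|^w (default w = 1) normalized over the in-set
  total, misses retreat by 1/(N−s); ES is the signed extremum. NES and the
  permutation p use gene-label permutations (default 1,000) of the same
  sign as ES, with the +1 continuity correction; sample permutation is
  impossible from a preranked list. Null p-values are verified uniform.
- **Trait comparisons**: Shapiro–Wilk decides between Student/paired t
  (both groups normal) and the two-sided Wilcoxon tests, exact null up to
  n = 25 per group, normal approximation beyond.

## Validation

A signature is evaluated on a cohort by keeping the cohort features whose
symbol is in the signature (duplicate symbols keep all matching features;
coverage is reported), then scoring logistic regression (lbfgs), RBF-SVM
(gamma = 1/n_features) or a default decision tree under repeated
stratified 5-fold CV: per fold, features are standardized on the training
samples only, and held-out samples are scored by accuracy and the rank AUC
of the classifier's continuous decision score. Results are mean ± SD over
folds × repeats (per-fold averaging; pooling scores per repeat would be
the alternative). `compare_signatures` adds a FULL baseline (all cohort
features) and a two-sided t-test between configurations on per-run AUCs.

## Synthetic cohorts

The generator emulates the study conditions: 16 vs 26 samples, three
blocks (10,000 genes / 943 proteins / 2,637 peptides at study scale,
scalable down), MCAR missingness at 26.45 % / 38.94 % in the MS blocks,
and continuous traits correlated with the dominant latent factor (defaults
r = 0.74, 0.64, −0.62 — the component-1/trait correlations reported for
the real cohort).

The planted signal enters through a low-rank latent model: every
informative feature loads 1.0 on a shared factor whose class means differ
by δ, plus (when `latent_dim` > 1) 0.5 on a secondary, non-discriminative
factor, plus N(0, σ²) residual noise (σ = 1 by default). δ is calibrated
as effect_size · √(1 + 0.25 + σ²) so each planted feature's standardized
group difference equals `effect_size`. Because the signal is a shared
factor, informative features are correlated within and across blocks —
exactly the covariance structure the multiblock model exploits — and
cross-block identity overlap is emulated by giving a fraction of planted
features the same gene symbol in every block. Non-informative features are
pure noise with mildly heterogeneous variances. The cohort gives no
effect-size estimate for its discriminative features; the default of 2
within-class SDs was chosen once to put the synthetic cohort in the same
cleanly separable regime (CV AUC > 0.95) the real cohort exhibited.

Consequences to keep in mind when interpreting passing tests:

- planted features share one latent draw, so *within a single cohort*
  their test statistics are mutually correlated (at effect 0 they cluster
  around the realized class difference of the factor); only their
  across-replicate marginal distribution is the null t distribution;
- missingness is MCAR, whereas real MS missingness is partly
  intensity-dependent; planted features are drawn before missingness, so
  a planted feature can exceed the 50 % filter — the ground truth records
  which informative features survive, and recovery metrics are computed
  over survivors;
- no batch effects, probe-level noise, or reporter-ion chemistry are
  simulated; real-cohort performance claims cannot be inferred from these
  tests.

Traits are r·z + √(1−r²)·ε with z the standardized factor-1 score, so the
population correlation is exactly r (affine at |r| = 1).

## Reproducibility and scale

All randomness flows through explicit integer seeds; the pipeline derives
per-stage seeds by hashing the stage name into the global seed (CRC32 XOR,
reduced below 2^31), so adding a stage never perturbs earlier stages, and
re-running a config reproduces byte-identical outputs. Desk-scale defaults
(blocks of a few hundred to a thousand features, tens of CV repeats, 100–
200 resample copies) keep a full run and the acceptance script in the
minutes range; every count scales up to the study-scale settings by
configuration.

## Known limitations

- Binary outcomes only; no multi-class support.
- No missing-data-tolerant fitting: imputation is strictly upstream.
- The exact per-block normalization of the coupling term used by other
  multiblock implementations cannot be confirmed from the published
  account; the cyclic update documented above is the implemented contract,
  so loadings may differ in detail from other software even at identical
  settings.
- `enumerate_grid`'s published ranges and the design-matrix defaults are
  conventions of the reimplemented workflow, not universal optima.
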