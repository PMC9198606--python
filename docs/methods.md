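# Methods

This note records what each stage computes, the assumptions behind it, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## The synthetic study

Every analysis stage is validated against simulated data with planted,
recorded structure (`SyntheticTruth`). The generator emulates two linked data
sets drawn from one gene model.

**Gene model.** 1,200 genes with lognormal baseline rates (log-SD 1). Each of
the eight cell types (tumor, fibroblast, endothelial, myeloid, B, cytotoxic,
acinar, islet) owns 25 exclusive marker genes elevated by `2**marker_log2fc`
(default log2 FC = 2) in its own type; the first marker of each type is the
lineage reference gene later used by the communication score (EPCAM, COL1A2,
CDH5, ITGAM, MS4A1, CD3E, CPA1, NEUROD1), floored at a solid baseline so
reference ratios are stable. Ligand–receptor program genes (COL1A1, FN1,
COL8A1 → ITGA2 by default) are elevated in their sender/target types the same
way.

**Single-cell counts.** Negative binomial around the cell-type mean,
`var = μ + φ μ²` with dispersion φ = 0.3 — a UMI-like noise model with no gene
length term. 150 cells per type, two samples of origin (interleaved) so
per-sample conserved marker testing is exercisable.

**Bulk cohorts.** Each of 300 samples is a Dirichlet(10, …, 10) cell-fraction
mixture of the cell-type TPM profiles. On the log2 scale the generator adds:

- two planted module factors ("green": 20 fibroblast + 20 myeloid markers plus
  the LR program genes; "blue": 20 endothelial + 20 cytotoxic markers), each
  with expression loading 0.5 on a latent activity `z ~ N(class mean, 1)`;
- lognormal measurement noise (log2-SD 0.3);
- an additive per-cohort batch shift per gene (SD 0.3, 3 sub-cohorts).

Columns are then rescaled to TPM (sum 10⁶). Survival times are exponential
with log-hazard `0.7·z_green − 0.7·z_blue` on a baseline median of 365 days,
censored by an independent Uniform(0, c) time with c calibrated by
root-finding so the expected censoring fraction equals `censor_rate` (0.3).

**Sample classes.** Three planted classes shift the module-activity means:
class 0 at the origin, the others at ±s sign patterns with s = 4.5
within-class SDs. Two deliberate design choices live here. First, the sign
patterns are chosen so the class structure adds *zero covariance* between the
two module factors; with axis-aligned shifts the classes would anticorrelate
the modules (through both the factor mixture and the TPM compositional
constraint) strongly enough that an unsigned network merges them — an artifact
of the generator, not a pipeline failure. Second, s = 4.5 puts adjacent class
means ≈ 4.5σ apart along one factor axis (≈ 1% Bayes error), i.e. the classes
are *well separated*: subtype-recovery tests then measure the clustering
machinery rather than irreducible overlap. A shared-factor design cannot make
separation grow with gene count (the within-class factor noise is common to
all module genes), so the separation must be planted at the factor level.

**What the generator does not emulate.** Doublets, ambient RNA, copy-number
effects, gene-length biases, nonlinear batch effects, informative censoring,
spatial structure. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to every artifact of
real tissue data.

## Marker selection

QC removes cells whose log1p library size or log1p detected-gene count falls
more than 3 scaled MADs (1.4826 × MAD) below the median — lower tail only.
Normalization is log2(TPM+1). Marker ranking is a pooled two-sided Wilcoxon
rank-sum test per gene (cells of the type vs all others) with BH correction
within type; fold change is computed on the TPM scale with pseudocount 1.
A `conserved_by_sample` flag re-runs the test within each sample of origin and
combines conservatively (max p, min FC), for data where sample confounding is
a concern. The CCMG rule applies strict inequalities (FC > 2, unadjusted
p < 0.05, matching the stated rule; adjusted values are also reported) and
drops any gene qualifying in two or more types. MEMGs are the CCMGs of the
five microenvironmental identities.

## Coexpression network

Unsigned adjacency `|cor|^β`. The scale-free fit index bins the connectivity
vector into 10 equal-count bins and regresses log10 empirical density
(bin mass / bin width) on log10 bin-mean connectivity; the fit is
`R² × −sign(slope)` so only decreasing relationships score. β is the lowest
candidate power reaching fit 0.85, else the best-fitting power. TOM follows
the standard shared-neighbour formula with unit diagonal.

Module detection is average-linkage clustering of 1 − TOM with a **static**
height cut (default 0.995) — chosen over dynamic hybrid tree cutting because
it is fully specifiable, deterministic, and recovers planted blocks; the
height is configurable. Clusters under 30 genes become grey; modules whose
eigengenes correlate above 0.75 merge iteratively; labels are color names in
size order. Eigengenes are the first right-singular vector of the
gene-standardized module submatrix, unit-norm, sign-fixed so the mean gene–ME
correlation is positive. kWithin is normalized to the module maximum because a
0.5 hub threshold is only meaningful on a bounded scale; hub selection is the
strict conjunction kME > 0.5 and normalized kWithin > 0.5. Over-representation
is the hypergeometric upper tail with BH correction, set sizes limited to
[10, 500] by default.

## Survival statistics

The univariate Cox partial likelihood uses the Efron tie correction
(preferable under the heavy ties rounding can create) and Newton–Raphson with
tolerance 1e-9, max 50 iterations, step clipping at ±2 and a divergence guard
that flags monotone likelihoods instead of looping. Wald SEs come from the
observed information. Kaplan–Meier and the k-group log-rank test delegate to
lifelines; a vectorized two-group log-rank z-statistic (shared by maxstat and
its permutation test) is implemented in-package and checked against a naive
O(n²) implementation in the tests.

Maxstat considers every unique covariate value leaving at least `minprop`
(default 0.1) of the samples on each side, picks the split maximizing |z|, and
computes p by permuting the covariate (default 1,000 permutations, add-one
estimator) — exact in distribution at this scale, rather than the
Lausen–Schumacher approximation. Both the raw log-rank p at the selected
cutpoint and the selection-adjusted permutation p are reported, since KM
p-values at maxstat-selected cutoffs are otherwise optimistic.

DL meta-analysis implements the moment estimator
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))` and reduces to fixed-effect
inverse-variance pooling when Q ≤ k − 1; it is cross-checked against
statsmodels' DL implementation.

## TME subtyping

Consensus clustering standardizes genes (preventing high-expression genes from
dominating Euclidean distances — the standardization question was open and is
decided here), subsamples 80% of samples 500 times (200 in the pipeline run,
which is ample at n = 300), runs k-means with k-means++ and 10 restarts, and
forms `consensus_ij = co-clustered / co-sampled`. Final labels cut an
average-linkage tree of 1 − consensus at k. k defaults to the maximal relative
delta-area of the consensus CDF, but the pipeline pins k = 3 to mirror a
three-class subtype analysis. The silhouette filter uses 1 − consensus as the
distance, retains widths > 0, and assigns width 0 to singleton-cluster samples
(dropped, with a warning).

## Outcome predictors

"Five-layer" is read as input + 3 hidden + output; hidden sizes 64/32/16
(configurable — no sizes are prescribed anywhere, so the defaults are this
package's own). Each hidden layer applies batch normalization *before* ReLU;
the output is a single sigmoid unit initialized at zero so an untrained model
scores 0.5. Training is full-batch Adam (learning rate 0.01) on binary
cross-entropy for 400 iterations on a random 2/3 split, fully seeded;
inference uses the final epoch's batch statistics. Labels for the 1-year task
are death within 365 days vs follow-up beyond it; samples censored before the
horizon are excluded rather than imputed.

The risk score is the *mean* of β-weighted z-scores, `Σ_g β_g z_g / |G|`,
rather than a β-normalized weighted average, because Σβ can be zero or
negative with mixed-sign coefficients. Standardization constants are frozen at
training time so the score transfers to external cohorts on the training
scale. Which genes enter both predictors: the MEMGs belonging to the
prognostic modules (falling back to all MEMGs if fewer than 10).

## Cell–cell communication

Edge weights operationalize "largest average expression" as the product of
sender-ligand and target-receptor mean TPM (the mean-expression edge
convention); ties break lexicographically on (sender, target). The bulk score
uses pseudocount 1 by default to guard zero reference expression; pseudocount
0 reproduces the plain ratio formula exactly and restores exact √c scale
equivariance. Cox fits for the HR-weighted network run on standardized
log-scores (the score is a ratio statistic; the log stabilizes the HR
interpretation). The integrated HR is the geometric mean of per-cohort HRs,
and an edge is flagged when HR > 1 with p < 0.05 in every cohort. The bundled
ligand–receptor table and junction gene set are small synthetic demo files
(integrin/ECM pairs) for offline use, not a database export.

## Pipeline and batch adjustment

Cohort merging uses a per-gene location–scale adjustment (standardize within
batch, restore pooled mean/SD) on log2(TPM+1) values — a verifiable contract
chosen over full parametric empirical-Bayes adjustment; a moment-based EB
shrinkage of the per-batch parameters is available behind a flag. Identical
batches pass through unchanged and pooled gene means are preserved.

`run_pipeline` executes: markers → CCMG/MEMG → batch-adjusted combined cohort
→ network/modules → module-eigengene Cox + maxstat + KM/log-rank → hubs + ORA
→ consensus classes + silhouette → risk score + classifier + per-cohort Cox +
DL meta (over the internal test split and two external cohorts simulated from
the same population) → LR filtering, top connections, bulk scores and the
HR-weighted network. Every artifact carries the config hash; a manifest
records seeds, parameters and library versions; reruns with the same config
are byte-identical.

## Problem sizes and numerical notes

Default study sizes (1,200 genes, 1,200 cells, 3 × 100-sample cohorts, 1,000
maxstat permutations, 200 consensus resamples in the pipeline) were chosen so
the full pipeline completes in well under a minute and the entire validation
suite in a few minutes on one CPU, while keeping all recovery targets
attainable. Degenerate inputs are handled explicitly: zero-variance covariates
and single-class labels raise; zero-variance genes are dropped by the
good-genes filter; zero-width connectivity distributions skip a candidate
power with a warning; eventless cohorts are skipped in network integration.

## Known limitations

- Univariate hazard ratios are non-collapsible: with several active modules, a
  univariate Cox fit on one true activity is attenuated relative to its
  planted coefficient. Recovery checks therefore plant a single active module;
  pipeline HRs on scores should be read as marginal associations.
- The static tree cut can glue modules whose activities are strongly
  (anti)correlated; the generator avoids planting such correlation, and real
  data may require tuning `cut_height` or `merge_cor`.
- The neural classifier is a small full-batch network: adequate for
  hundreds-of-samples cohorts, not a tuned deep-learning model; no
  hyperparameter search is performed.
- Consensus clustering's delta-area criterion often prefers small k on weakly
  structured data; pinning k is recommended when a class count is hypothesized.
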