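# tmenet

Single-cell-informed coexpression deconvolution of bulk tumor transcriptomes,
built for pancreatic ductal adenocarcinoma (PDAC)-style studies where the
stroma dominates the tissue and bulk expression mixes many cell populations.
The package is for computational biologists who want to chain the full
workflow — cell-component marker genes from annotated single-cell data,
weighted coexpression modules of those markers in bulk cohorts, module-level
survival statistics, tumor-microenvironment (TME) subtypes, outcome
predictors, and ligand–receptor communication scoring — as a tested Python
library, with a synthetic-data generator that plants known structure so every
stage has an exact recovery target.

## The method

1. **Cell component marker genes (CCMGs).** In annotated single-cell data
   (log2(TPM+1)), each cell type is tested against all others per gene with a
   two-sided Wilcoxon rank-sum test; genes with fold change > 2 and p < 0.05
   in exactly one type get that unique identity. CCMGs whose identity is a
   microenvironmental type (B, cytotoxic/T, myeloid, endothelial, fibroblast)
   form the TME marker-gene set (MEMGs).
2. **Weighted coexpression network.** On bulk cohorts (merged with a
   location–scale batch adjustment), an unsigned network over the CCMGs:
   adjacency `a_ij = |cor(x_i, x_j)|^β` with β the lowest power whose signed
   scale-free fit R² reaches 0.85; topological overlap
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`; modules by
   average-linkage clustering of 1 − TOM with a static cut and eigengene
   merging. Each module is summarized by its eigengene (ME, first principal
   component); genes with module membership kME > 0.5 and normalized
   intramodular connectivity kWithin > 0.5 are hub genes.
3. **Survival statistics.** Univariate Cox regression (Efron ties,
   Newton–Raphson on the partial likelihood), Kaplan–Meier curves, log-rank
   tests, maximally selected rank-statistic cutpoints with permutation
   p-values, and DerSimonian–Laird random-effects meta-analysis of per-cohort
   log hazard ratios.
4. **TME subtypes.** Consensus k-means (Euclidean, k-means++ restarts) over
   subsampled bulk samples on MEMG expression; the co-clustering frequency
   matrix drives the final partition and a per-sample silhouette filter
   (retain width > 0).
5. **Outcome predictors.** A risk score — the mean of Cox-coefficient-weighted,
   standardized MEMG expression — and a five-layer neural classifier (input,
   three batch-normalized ReLU hidden layers, sigmoid output; full-batch Adam,
   400 iterations, 2/3 training split) for 1-year survival, evaluated by
   rank-based AUC.
6. **Cell–cell communication.** Single-cell edge weights
   `mean(ligand TPM | sender) × mean(receptor TPM | target)` for every ordered
   cell-type pair; the top connection per ligand–receptor pair; a bulk
   communication score `sqrt((L/L_ref) · (R/R_ref))` with per-cell-type
   reference genes (tumor EPCAM, endothelial CDH5, fibroblast COL1A2, myeloid
   ITGAM, acinar CPA1, islet NEUROD1, B MS4A1, cytotoxic CD3E); and an
   HR-weighted network pooling per-cohort Cox fits of the score.

## Worked example

`examples/04_survival_statistics.py` fits the survival layer on a synthetic
cohort whose green-module activity carries a true log hazard ratio of 0.7
(HR 2.014) and pools three cohorts:

```
Cox on planted activity: HR=1.907 [1.769, 2.055], p=7.83e-64
(true log HR = 0.7, estimated 0.645 +- 0.038)

maxstat cutpoint 1.393 (|z|=18.90, permutation p=0.0010, 210 low / 90 high)
log-rank high vs low: chi2=357.2 (df=1), p=1.12e-79
  KM median survival (low): 1636 days
  KM median survival (high): 24 days

DL meta-analysis of 3 cohorts: pooled HR=2.015 [1.893, 2.144], tau2=0.0012, p=8.50e-108
```

The pooled hazard ratio lands on the planted 2.014 with τ² ≈ 0, as expected
when the cohorts share one true effect. The other scripts in `examples/` walk
through each stage the same way (simulation, marker catalog, network modules,
subtypes, predictors, communication), and `examples/08_full_pipeline.py` runs
everything end to end, printing a planted-truth scorecard (marker sensitivity,
module/class recovery ARI, held-out AUC, planted communication edges).

A thin CLI mirrors the stages for shell use:

```sh
tmenet simulate --seed 1 --out-dir data/
tmenet markers --sc-dir data/sc --out-dir out/
tmenet run-all --seed 1 --out-dir out/
```

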