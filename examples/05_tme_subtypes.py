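"""Consensus k-means subtyping of bulk samples on TME marker genes, the
silhouette filter, and survival differences between the recovered classes.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from tmenet import (
    ExpressionMatrix, SimConfig, batch_adjust, consensus_cluster,
    log_tpm_normalize, logrank_test, qc_filter_cells, rank_markers,
    select_ccmgs, silhouette_filter, simulate_bulk_cohort, simulate_single_cell,
)

cfg = SimConfig(seed=1)
counts, ann, _ = simulate_single_cell(cfg)
counts = qc_filter_cells(counts)
ccmg = select_ccmgs(rank_markers(log_tpm_normalize(counts), ann.loc[counts.columns]))

bulk, surv, batches, truth = simulate_bulk_cohort(cfg)
adjusted = batch_adjust(
    ExpressionMatrix(np.log2(bulk.values + 1.0), "log2tpm1"), batches)

# cluster samples on the MEMGs that belong to planted modules
memg_genes = [g for g in ccmg.index[ccmg["memg"]] if g in truth.module_map]
res = consensus_cluster(adjusted.subset_genes(memg_genes),
                        k_range=(2, 3, 4), n_resamples=200, seed=1, fixed_k=3)
labels = res.labels[res.chosen_k]
retained, widths = silhouette_filter(res.consensus[res.chosen_k], labels)

print(f"consensus clustering at k={res.chosen_k} on {len(memg_genes)} MEMGs")
print(labels.value_counts().to_string())
print(f"silhouette filter retained {len(retained)}/{len(labels)} samples "
      f"(width > 0)")
ari = adjusted_rand_score(truth.class_labels.loc[retained], labels.loc[retained])
print(f"adjusted Rand index vs planted classes: {ari:.3f}")

chi2, df, p = logrank_test(surv.loc[retained], labels.loc[retained])
print(f"log-rank across TME classes: chi2={chi2:.1f} (df={df}), p={p:.2e}")
# A significant log-rank confirms the recovered classes differ in outcome, as
# planted through the class-specific module activities.
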