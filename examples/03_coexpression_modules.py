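"""Weighted coexpression network on the marker genes in bulk data: soft
threshold by scale-free fit, adjacency/TOM, module detection, eigengenes,
intramodular connectivity and hub genes.
"""

import numpy as np

from tmenet import (
    ExpressionMatrix, SimConfig, batch_adjust, build_network,
    connectivity_stats, detect_modules, filter_good_genes_samples,
    log_tpm_normalize, module_eigengenes, pick_soft_threshold, qc_filter_cells,
    rank_markers, select_ccmgs, select_hubs, simulate_bulk_cohort,
    simulate_single_cell,
)

cfg = SimConfig(seed=1)
counts, ann, _ = simulate_single_cell(cfg)
counts = qc_filter_cells(counts)
ccmg = select_ccmgs(rank_markers(log_tpm_normalize(counts), ann.loc[counts.columns]))

bulk, surv, batches, truth = simulate_bulk_cohort(cfg)
log_bulk = ExpressionMatrix(np.log2(bulk.values + 1.0), "log2tpm1")
adjusted = batch_adjust(log_bulk, batches)

net = filter_good_genes_samples(adjusted.subset_genes(ccmg.index))
power, fit_table = pick_soft_threshold(net)
print(f"soft threshold beta = {power:g} "
      f"(lowest power with signed scale-free fit >= 0.85)")

adjacency, tom = build_network(net, power)
modules = detect_modules(tom, net)
print("\nmodule sizes:")
print(modules.value_counts().to_string())

eigengenes = module_eigengenes(net, modules)
hub_table = connectivity_stats(net, adjacency, modules, eigengenes)
hubs = select_hubs(hub_table)  # kME > 0.5 and normalized kWithin > 0.5
print(f"\n{len(hubs)} hub genes; the 5 best by kME:")
print(hub_table.loc[hubs].nlargest(5, "kme").round(3).to_string())

act = truth.module_activity
for m in act.columns:
    best = max(abs(np.corrcoef(eigengenes.loc[me, act.index], act[m])[0, 1])
               for me in eigengenes.index)
    print(f"best |cor| of a recovered eigengene with planted factor {m!r}: {best:.3f}")
# Values near 1 show the module eigengene is an accurate readout of the
# planted latent activity driving those genes.
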