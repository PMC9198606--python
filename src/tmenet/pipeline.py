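"""End-to-end orchestration: cohort integration, all analysis stages, and a
planted-truth scorecard.

``run_pipeline`` drives the full chain on a synthetic study: single-cell
markers -> CCMG/MEMG catalogs -> batch-adjusted combined bulk cohort ->
coexpression modules -> module-eigengene survival statistics -> hub genes and
over-representation -> consensus TME classes -> risk score and neural
classifier with meta-analysis across held-out cohorts -> ligand-receptor
filtering, top connections, bulk communication scores and the HR-weighted
network. Every artifact (and a machine-readable manifest) can be written to an
output directory, and because the inputs are simulated, the result bundle
carries a scorecard of planted-truth recovery.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as tio
from .containers import CELL_TYPES, ExpressionMatrix, to_tpm
from .coexpression import (
    NetworkParams, build_network, connectivity_stats, detect_modules,
    filter_good_genes_samples, module_eigengenes, ora_enrichment,
    pick_soft_threshold, select_hubs,
)
from .communication import (
    alluvial_weights, comm_network_integrate, demo_junction_genes,
    demo_lr_pairs, filter_hub_junction_pairs, sc_edge_weights, top_connections,
)
from .markers import (
    log_tpm_normalize, qc_filter_cells, rank_markers, select_ccmgs, select_memgs,
)
from .predictors import (
    MLPConfig, apply_risk_score, fit_risk_score, label_one_year_survival,
    predict_mlp, roc_auc, train_mlp,
)
from .simulate import SimConfig, SyntheticTruth, simulate_bulk_cohort, simulate_single_cell
from .subtyping import abundance_score, compare_classes, consensus_cluster, silhouette_filter
from .survival import (
    CoxFit, dl_meta, fit_cox_univariate, kaplan_meier, logrank_test, maxstat_cutpoint,
)


def batch_adjust(
    expr: ExpressionMatrix,
    batches: pd.Series,
    empirical_bayes: bool = False,
) -> ExpressionMatrix:
    """Location-scale cross-batch adjustment on the current (log) scale.

    Per gene: values are standardized within each batch and re-expressed on
    the pooled mean/SD, removing additive and multiplicative batch effects.
    With ``empirical_bayes=True``, per-batch means and SDs are first shrunk
    toward their across-gene batch averages (moment-based), which stabilizes
    genes with few samples per batch. Identical batches pass through unchanged.
    """
    batches = batches.loc[expr.columns]
    levels = pd.unique(batches)
    if len(levels) < 2:
        raise ValueError("batch adjustment needs at least two batches")
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError(f"batch(es) with a single sample: "
                         f"{list(counts[counts < 2].index)}")
    arr = expr.values.to_numpy(dtype=float)
    pooled_mu = arr.mean(axis=1, keepdims=True)
    pooled_sd = arr.std(axis=1, keepdims=True)
    out = np.empty_like(arr)
    for b in levels:
        cols = np.flatnonzero((batches == b).to_numpy())
        block = arr[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        if empirical_bayes:
            n_b = len(cols)
            for stat in (mu, sd):
                grand = stat.mean()
                tau2 = max(stat.var() - stat.var() / n_b, 1e-12)
                w = tau2 / (tau2 + stat.var() / n_b)
                stat[:] = w * stat + (1 - w) * grand
        safe_sd = np.where(sd > 0, sd, 1.0)
        z = (block - mu) / safe_sd
        adj = z * pooled_sd + pooled_mu
        out[:, cols] = np.where(sd > 0, adj, pooled_mu)
    vals = pd.DataFrame(out, index=expr.genes, columns=expr.columns)
    return ExpressionMatrix(vals, expr.scale)


@dataclass
class PipelineConfig:
    """Parameters of the full synthetic-study pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_external_cohorts: int = 2
    # marker selection
    fc_min: float = 2.0
    p_max: float = 0.05
    # network
    network: NetworkParams = field(default_factory=NetworkParams)
    hub_kme_min: float = 0.5
    hub_kwithin_min: float = 0.5
    module_alpha: float = 0.05          # prognostic-module significance level
    # subtyping
    k_range: Tuple[int, ...] = (2, 3, 4)
    fixed_k: Optional[int] = 3
    consensus_resamples: int = 200
    consensus_subsample: float = 0.8
    # survival / predictors
    maxstat_minprop: float = 0.1
    maxstat_nperm: int = 1000
    horizon: float = 365.0
    mlp: MLPConfig = field(default_factory=MLPConfig)
    comm_pseudocount: float = 1.0
    seed: Optional[int] = None           # defaults to sim.seed
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            self.seed = self.sim.seed

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of every stage's principal outputs plus the recovery scorecard."""

    ccmg: pd.DataFrame
    memg: pd.DataFrame
    modules: pd.Series
    eigengenes: pd.DataFrame
    power: float
    module_cox: pd.DataFrame
    prognostic_modules: List[str]
    hub_table: pd.DataFrame
    hubs: List[str]
    ora: pd.DataFrame
    tme_labels: pd.Series
    silhouette: pd.Series
    retained_samples: List[str]
    class_logrank: Tuple[float, int, float]
    abundance: pd.DataFrame
    class_diff: pd.DataFrame
    risk_model: object
    dnn_model: object
    aucs: Dict[str, float]
    dnn_meta: object
    risk_meta: object
    top_edges: pd.DataFrame
    comm_network: pd.DataFrame
    alluvial_molecules: pd.DataFrame
    alluvial_celltypes: pd.Series
    scorecard: Dict[str, float]
    manifest: Dict[str, object]


def _module_ari(modules: pd.Series, truth: SyntheticTruth) -> float:
    planted = [g for g in truth.module_map if g in modules.index]
    if not planted:
        return float("nan")
    true_lab = [truth.module_map[g] for g in planted]
    return float(adjusted_rand_score(true_lab, modules.loc[planted].tolist()))


def _eigengene_factor_cor(eigengenes: pd.DataFrame, modules: pd.Series,
                          truth: SyntheticTruth) -> float:
    """Min over planted modules of the best |cor| of any recovered ME with the
    planted latent factor."""
    if truth.module_activity is None or eigengenes.empty:
        return float("nan")
    best = []
    act = truth.module_activity.loc[eigengenes.columns]
    for m in act.columns:
        z = act[m].to_numpy(dtype=float)
        cors = [abs(np.corrcoef(eigengenes.loc[me], z)[0, 1]) for me in eigengenes.index]
        best.append(max(cors))
    return float(min(best))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage on a simulated study; see the module docstring."""
    rng_seed = int(cfg.seed)

    # --- single-cell stage ---------------------------------------------------
    sc_counts, sc_ann, sc_truth = simulate_single_cell(cfg.sim)
    sc_counts = qc_filter_cells(sc_counts)
    sc_ann = sc_ann.loc[sc_counts.columns]
    sc_expr = log_tpm_normalize(sc_counts)
    marker_table = rank_markers(sc_expr, sc_ann)
    ccmg = select_ccmgs(marker_table, fc_min=cfg.fc_min, p_max=cfg.p_max)
    memg = select_memgs(ccmg)

    # --- bulk cohorts ---------------------------------------------------------
    bulk, surv, batches, truth = simulate_bulk_cohort(cfg.sim, seed_offset=0)
    log_bulk = ExpressionMatrix(np.log2(bulk.values + 1.0), "log2tpm1")
    adjusted = batch_adjust(log_bulk, batches)

    externals: Dict[str, Tuple[ExpressionMatrix, pd.DataFrame]] = {}
    for e in range(1, cfg.n_external_cohorts + 1):
        ebulk, esurv, ebatch, _ = simulate_bulk_cohort(cfg.sim, seed_offset=e)
        elog = ExpressionMatrix(np.log2(ebulk.values + 1.0), "log2tpm1")
        externals[f"external{e}"] = (batch_adjust(elog, ebatch), esurv)

    # --- coexpression network on CCMGs ---------------------------------------
    net_expr = filter_good_genes_samples(adjusted.subset_genes(ccmg.index))
    if cfg.network.power is None:
        power, _fit_table = pick_soft_threshold(
            net_expr, cfg.network.candidate_powers, cfg.network.target_r2)
    else:
        power = float(cfg.network.power)
    adjacency, tom = build_network(net_expr, power)
    modules = detect_modules(tom, net_expr, cfg.network)
    eigengenes = module_eigengenes(net_expr, modules)
    hub_table = connectivity_stats(net_expr, adjacency, modules, eigengenes)

    # --- module-eigengene survival statistics --------------------------------
    module_rows = []
    km_curves = {}
    for mod in eigengenes.index:
        me = eigengenes.loc[mod]
        fit = fit_cox_univariate(me, surv)
        cut = maxstat_cutpoint(me, surv, minprop=cfg.maxstat_minprop,
                               n_perm=cfg.maxstat_nperm, seed=rng_seed)
        groups = pd.Series(np.where(me > cut.cutpoint, "high", "low"), index=me.index)
        chi2, df, lr_p = logrank_test(surv, groups)
        km_curves[mod] = kaplan_meier(surv, groups)
        module_rows.append({
            "module": mod, "size": int((modules == mod).sum()),
            "beta": fit.beta, "hr": fit.hr, "se": fit.se, "p": fit.p,
            "cutpoint": cut.cutpoint, "maxstat_stat": cut.statistic,
            "maxstat_p": cut.p, "logrank_chi2": chi2, "logrank_p": lr_p,
        })
    module_cox = pd.DataFrame(module_rows).set_index("module")
    prognostic = module_cox.index[module_cox["p"] < cfg.module_alpha].tolist()
    if not prognostic:
        warnings.warn("no prognostic module at the configured alpha; "
                      "using the two smallest-p modules")
        prognostic = module_cox["p"].nsmallest(2).index.tolist()

    hubs = select_hubs(hub_table, cfg.hub_kme_min, cfg.hub_kwithin_min,
                       modules=prognostic)

    # over-representation of hub genes against cell-type marker sets plus the
    # bundled junction/communication sets
    marker_sets = {f"{ct}_markers": ccmg.index[ccmg["identity"] == ct].tolist()
                   for ct in CELL_TYPES}
    collection = {k: v for k, v in marker_sets.items() if len(v) >= 5}
    collection["CELL_JUNCTION_ORGANIZATION"] = demo_junction_genes()
    ora = ora_enrichment(hubs, collection, universe=net_expr.genes, min_size=5)

    # --- TME subtyping on prognostic-module MEMGs -----------------------------
    memg_genes = [g for g in memg.index if modules.get(g, "grey") in prognostic]
    if len(memg_genes) < 10:
        warnings.warn("fewer than 10 prognostic-module MEMGs; using all MEMGs")
        memg_genes = [g for g in memg.index if g in adjusted.genes]
    sub_expr = adjusted.subset_genes(memg_genes)
    cons = consensus_cluster(sub_expr, k_range=cfg.k_range,
                             n_resamples=cfg.consensus_resamples,
                             subsample=cfg.consensus_subsample,
                             seed=rng_seed, fixed_k=cfg.fixed_k)
    labels = cons.labels[cons.chosen_k]
    retained, widths = silhouette_filter(cons.consensus[cons.chosen_k], labels)
    class_logrank = logrank_test(surv.loc[retained], labels.loc[retained])

    abund = abundance_score(adjusted, {ct: ccmg.index[ccmg["identity"] == ct]
                                       for ct in CELL_TYPES})
    top2 = labels.loc[retained].value_counts().index[:2]
    two_class = labels.loc[retained][labels.loc[retained].isin(top2)]
    class_diff = compare_classes(abund.loc[:, two_class.index], two_class)

    # --- outcome predictors ---------------------------------------------------
    labels_1y = label_one_year_survival(surv, horizon=cfg.horizon)
    features = adjusted.values.loc[memg_genes].T  # samples x genes
    mlp_cfg = MLPConfig(**{**asdict(cfg.mlp), "seed": rng_seed})
    dnn = train_mlp(features.loc[labels_1y.index], labels_1y, mlp_cfg)
    train_ids = [s for s in dnn.train_index]
    test_ids = [s for s in dnn.test_index]
    dnn_scores = predict_mlp(dnn, features)
    aucs = {
        "dnn_train": roc_auc(dnn_scores.loc[train_ids], labels_1y.loc[train_ids]),
        "dnn_test": roc_auc(dnn_scores.loc[test_ids], labels_1y.loc[test_ids]),
    }

    risk_model = fit_risk_score(adjusted, memg_genes, surv)
    risk_scores = apply_risk_score(risk_model, adjusted)

    def _cox_of_score(score: pd.Series, s: pd.DataFrame) -> CoxFit:
        x = score.loc[s.index].to_numpy(dtype=float)
        return fit_cox_univariate((x - x.mean()) / x.std(), s)

    dnn_fits, risk_fits = [], []
    ext_dnn_aucs, ext_risk_aucs = [], []
    for name, (eexpr, esurv) in externals.items():
        feats = eexpr.values.loc[memg_genes].T
        escore = predict_mlp(dnn, feats)
        erisk = apply_risk_score(risk_model, eexpr)
        elab = label_one_year_survival(esurv, horizon=cfg.horizon)
        ext_dnn_aucs.append(roc_auc(escore.loc[elab.index], elab))
        ext_risk_aucs.append(roc_auc(erisk.loc[elab.index], elab))
        dnn_fits.append(_cox_of_score(escore, esurv))
        risk_fits.append(_cox_of_score(erisk, esurv))
    dnn_fits.append(_cox_of_score(dnn_scores.loc[test_ids], surv.loc[test_ids]))
    risk_fits.append(_cox_of_score(risk_scores, surv))
    aucs["dnn_external"] = float(np.mean(ext_dnn_aucs)) if ext_dnn_aucs else float("nan")
    aucs["risk_external"] = float(np.mean(ext_risk_aucs)) if ext_risk_aucs else float("nan")
    aucs["risk_all"] = roc_auc(risk_scores.loc[labels_1y.index], labels_1y)
    dnn_meta = dl_meta([f.beta for f in dnn_fits], [f.se for f in dnn_fits])
    risk_meta = dl_meta([f.beta for f in risk_fits], [f.se for f in risk_fits])

    # --- cell-cell communication ----------------------------------------------
    lr = demo_lr_pairs()
    planted = truth.lr_truth[["ligand", "receptor"]]
    lr = pd.concat([lr, planted], ignore_index=True).drop_duplicates().reset_index(drop=True)
    junction = set(demo_junction_genes()) | set(planted["ligand"]) | set(planted["receptor"])
    lr_used = filter_hub_junction_pairs(lr, hubs, junction)
    if lr_used.empty:
        lr_used = lr  # keep the stage exercised even if hub selection was unlucky
    edges = sc_edge_weights(to_tpm(sc_expr), sc_ann, lr_used)
    top = top_connections(edges)
    cohorts = {"combined": (to_tpm(adjusted), surv)}
    for name, (eexpr, esurv) in externals.items():
        cohorts[name] = (to_tpm(eexpr), esurv)
    comm_net = comm_network_integrate(top, cohorts, pseudocount=cfg.comm_pseudocount)
    mol_w, cell_w = alluvial_weights(top, to_tpm(sc_expr), sc_ann)

    # --- scorecard against planted truth --------------------------------------
    recovered = set(ccmg.index)
    true_markers = set(truth.marker_map)
    correct = sum(1 for g in recovered & true_markers
                  if ccmg.loc[g, "identity"] == truth.marker_map[g])
    false_identity = sum(1 for g in recovered
                         if truth.marker_map.get(g) is not None
                         and ccmg.loc[g, "identity"] != truth.marker_map[g])
    false_identity += sum(1 for g in recovered if g not in true_markers)

    planted_programs = truth.lr_truth
    hits = 0
    planted_hrs, planted_ps = [], []
    for _, prog in planted_programs.iterrows():
        row = top[(top["ligand"] == prog["ligand"]) & (top["receptor"] == prog["receptor"])]
        if len(row) and not row["no_connection"].iloc[0] \
                and row["sender"].iloc[0] == prog["sender"] \
                and row["target"].iloc[0] == prog["target"]:
            hits += 1
        net_row = comm_net[(comm_net["ligand"] == prog["ligand"])
                           & (comm_net["receptor"] == prog["receptor"])]
        if len(net_row):
            planted_hrs.append(float(net_row["integrated_hr"].iloc[0]))
            pcols = [c for c in net_row.columns if c.startswith("p_")]
            planted_ps.append(float(net_row[pcols].max(axis=1).iloc[0]))

    true_classes = truth.class_labels.loc[retained]
    scorecard = {
        "marker_sensitivity": correct / len(true_markers),
        "marker_false_identity": false_identity / max(len(recovered), 1),
        "module_ari": _module_ari(modules, truth),
        "eigengene_factor_cor": _eigengene_factor_cor(eigengenes, modules, truth),
        "class_ari": float(adjusted_rand_score(true_classes, labels.loc[retained])),
        "silhouette_retention": len(retained) / len(labels),
        "class_logrank_p": class_logrank[2],
        "dnn_auc_train": aucs["dnn_train"],
        "dnn_auc_test": aucs["dnn_test"],
        "dnn_auc_external": aucs["dnn_external"],
        "risk_auc_external": aucs["risk_external"],
        "dnn_meta_hr": dnn_meta.pooled_hr,
        "risk_meta_hr": risk_meta.pooled_hr,
        "top_connection_hits": hits / max(len(planted_programs), 1),
        "planted_edge_hr_min": min(planted_hrs) if planted_hrs else float("nan"),
        "planted_edge_p_max": max(planted_ps) if planted_ps else float("nan"),
    }

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": rng_seed,
        "sim_seed": cfg.sim.seed,
        "power": power,
        "chosen_k": cons.chosen_k,
        "prognostic_modules": prognostic,
        "n_hubs": len(hubs),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "parameters": json.loads(json.dumps(asdict(cfg), default=str)),
    }

    result = PipelineResult(
        ccmg=ccmg, memg=memg, modules=modules, eigengenes=eigengenes, power=power,
        module_cox=module_cox, prognostic_modules=prognostic,
        hub_table=hub_table, hubs=hubs, ora=ora,
        tme_labels=labels, silhouette=widths, retained_samples=list(retained),
        class_logrank=class_logrank, abundance=abund, class_diff=class_diff,
        risk_model=risk_model, dnn_model=dnn, aucs=aucs,
        dnn_meta=dnn_meta, risk_meta=risk_meta,
        top_edges=top, comm_network=comm_net,
        alluvial_molecules=mol_w, alluvial_celltypes=cell_w,
        scorecard=scorecard, manifest=manifest,
    )
    if cfg.out_dir is not None:
        _write_artifacts(cfg, result, sc_counts, sc_ann, bulk, surv, batches, truth)
    return result


def _write_tsv(df, path, config_hash: str, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tmenet config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _write_artifacts(cfg, res, sc_counts, sc_ann, bulk, surv, batches, truth) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    tio.write_mtx(sc_counts, out / "sc")
    tio.write_annotation_tsv(sc_ann, out / "sc" / "annotation.tsv")
    tio.write_bulk_tsv(bulk, out / "bulk_tpm.tsv")
    tio.write_survival_csv(surv, out / "survival.csv")
    batches.to_frame().to_csv(out / "batches.csv", index_label="sample")
    truth.to_json(out / "truth.json")
    _write_tsv(res.ccmg, out / "ccmg_catalog.tsv", h, "gene")
    _write_tsv(res.modules.to_frame(), out / "module_assignment.tsv", h, "gene")
    _write_tsv(res.eigengenes, out / "eigengenes.tsv", h, "module")
    _write_tsv(res.module_cox, out / "module_survival.tsv", h, "module")
    _write_tsv(res.hub_table, out / "hub_table.tsv", h, "gene")
    _write_tsv(res.ora, out / "ora.tsv", h, "rank")
    _write_tsv(pd.DataFrame({"tme_class": res.tme_labels,
                             "silhouette": res.silhouette}),
               out / "tme_classes.tsv", h, "sample")
    _write_tsv(res.top_edges, out / "top_connections.tsv", h, "rank")
    _write_tsv(res.comm_network, out / "comm_network.tsv", h, "rank")
    res.risk_model.to_json(out / "risk_model.json")
    res.dnn_model.to_json(out / "dnn_model.json")
    (out / "scorecard.json").write_text(json.dumps(res.scorecard, indent=1))
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=1, default=str))
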