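"""Weighted gene coexpression network analysis.

Implements the unsigned weighted-network workflow: soft-threshold selection by
scale-free fit, adjacency ``|cor|^beta``, topological overlap (TOM), module
detection by average-linkage clustering of 1 - TOM with a static height cut and
eigengene-based merging, module eigengenes, intramodular connectivity and
module membership, hub-gene selection, and hypergeometric over-representation
of gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

#: Module labels in size order, following the coexpression-network convention
#: of naming modules by color (grey is reserved for unassigned genes).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

GREY = "grey"


@dataclass
class NetworkParams:
    """Tunables of the network construction and module detection."""

    power: Optional[float] = None            # soft threshold beta; picked if None
    candidate_powers: Sequence[float] = field(default_factory=lambda: tuple(range(1, 21)))
    target_r2: float = 0.85                  # scale-free fit target
    min_module_size: int = 30
    merge_cor: float = 0.75                  # eigengene correlation above which modules merge
    cut_height: float = 0.995                # static tree cut height on 1 - TOM

    def __post_init__(self) -> None:
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        for name in ("target_r2", "merge_cor", "cut_height"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def filter_good_genes_samples(
    expr: ExpressionMatrix, max_missing: float = 0.5
) -> ExpressionMatrix:
    """Iteratively drop zero-variance / mostly-missing genes and samples."""
    vals = expr.values
    while True:
        arr = vals.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        gene_ok = finite.mean(axis=1) >= 1 - max_missing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(np.where(finite, arr, np.nan), axis=1)
        gene_ok &= np.nan_to_num(var) > 0
        sample_ok = finite.mean(axis=0) >= 1 - max_missing
        if gene_ok.all() and sample_ok.all():
            break
        vals = vals.loc[gene_ok, sample_ok]
        if vals.shape[0] == 0:
            raise ValueError("all genes removed by the good-genes filter")
    out = expr.copy()
    out.values = vals
    return out


def scale_free_fit_index(k: np.ndarray, nbins: int = 10) -> Tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Connectivities are split into ``nbins`` equal-count bins; the empirical
    density of each bin (bin mass / bin width) is regressed on log10 of the
    bin-mean connectivity. Returns ``(R^2 * -sign(slope), slope)`` so that a
    decreasing log-log relationship (the scale-free signature) scores
    positively.
    """
    k = np.sort(np.asarray(k, dtype=float))
    if k[-1] - k[0] <= 0:
        raise ValueError("degenerate connectivity: all values equal")
    edges = np.quantile(k, np.linspace(0, 1, nbins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("degenerate connectivity: too few distinct values")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    mean_k, dens = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if sel.sum() == 0 or width <= 0:
            continue
        mean_k.append(k[sel].mean())
        dens.append(sel.mean() / width)
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(dens))
    if len(x) < 3:
        raise ValueError("degenerate connectivity: too few usable bins")
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r * r * -np.sign(slope)), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidate_powers: Sequence[float] = tuple(range(1, 21)),
    target_r2: float = 0.85,
    nbins: int = 10,
) -> Tuple[float, pd.DataFrame]:
    """Choose the soft threshold: lowest power whose signed scale-free fit
    reaches ``target_r2``; if none does, the power with the best fit.

    Returns the chosen power and the full fit table (power, fit, mean_k).
    """
    if expr.n_genes < 20:
        raise ValueError("need at least 20 genes to assess scale-free fit")
    cor = np.corrcoef(expr.values.to_numpy(dtype=float))
    acor = np.abs(cor)
    rows = []
    for beta in candidate_powers:
        a = acor ** beta
        k = a.sum(axis=1) - 1.0  # exclude self
        try:
            fit, slope = scale_free_fit_index(k, nbins=nbins)
        except ValueError as err:
            warnings.warn(f"power {beta}: {err}; skipped")
            fit, slope = np.nan, np.nan
        rows.append({"power": beta, "fit": fit, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= target_r2]
    if len(ok):
        power = float(ok["power"].iloc[0])
    else:
        if table["fit"].isna().all():
            raise ValueError("scale-free fit undefined at every candidate power")
        power = float(table.loc[table["fit"].idxmax(), "power"])
    return power, table


def build_network(
    expr: ExpressionMatrix, power: float
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Unsigned adjacency and topological overlap matrices.

    ``a_ij = |cor(x_i, x_j)|^power`` (unit diagonal) and
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with the
    shared-neighbour sum taken over ``u != i, j`` and unit diagonal.
    """
    cor = np.corrcoef(expr.values.to_numpy(dtype=float))
    if not np.isfinite(cor).all():
        bad = expr.genes[~np.isfinite(cor).all(axis=1)]
        raise ValueError(f"non-finite correlations for genes: {list(bad[:5])}")
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    shared = a @ a - 2.0 * a  # remove u=i and u=j terms (diagonal is 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    genes = expr.genes
    return (
        pd.DataFrame(a, index=genes, columns=genes),
        pd.DataFrame(tom, index=genes, columns=genes),
    )


def _size_ordered_labels(assign: pd.Series) -> pd.Series:
    sizes = assign[assign != GREY].value_counts()
    mapping = {}
    for i, lab in enumerate(sizes.index):
        mapping[lab] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    return assign.map(lambda m: mapping.get(m, GREY))


def detect_modules(
    tom: pd.DataFrame,
    expr: Optional[ExpressionMatrix] = None,
    params: Optional[NetworkParams] = None,
) -> pd.Series:
    """Assign genes to modules by static-cut clustering of the TOM dissimilarity.

    Average-linkage hierarchical clustering of ``1 - TOM`` is cut at
    ``params.cut_height``; clusters smaller than ``params.min_module_size``
    become grey; modules whose eigengenes correlate above ``params.merge_cor``
    are merged iteratively (requires ``expr``; skipped with a warning when the
    expression matrix is not supplied). Labels are color names in decreasing
    size order.
    """
    params = params or NetworkParams()
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    raw = fcluster(link, t=params.cut_height, criterion="distance")
    assign = pd.Series(raw.astype(str), index=tom.index, name="module")
    sizes = assign.value_counts()
    assign[assign.map(sizes) < params.min_module_size] = GREY

    if (assign == GREY).all():
        warnings.warn("module detection produced only grey genes")
        return assign

    if expr is not None:
        while True:
            mes = module_eigengenes(expr, assign)
            if mes.shape[0] < 2:
                break
            cor = np.corrcoef(mes.to_numpy())
            np.fill_diagonal(cor, -np.inf)
            i, j = np.unravel_index(np.argmax(cor), cor.shape)
            if cor[i, j] <= params.merge_cor:
                break
            a, b = mes.index[i], mes.index[j]
            assign[assign == b] = a
    else:
        warnings.warn("no expression matrix supplied; eigengene merge step skipped")

    return _size_ordered_labels(assign)


def module_eigengenes(expr: ExpressionMatrix, modules: pd.Series) -> pd.DataFrame:
    """First principal component (over samples) of each module's genes.

    Genes are standardized across samples first; each eigengene has unit norm
    and its sign is fixed so the mean correlation with its module's genes is
    positive. Returns a module x sample matrix.
    """
    vals = expr.values
    out = {}
    for mod in [m for m in modules.unique() if m != GREY]:
        genes = modules.index[modules == mod]
        sub = vals.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        if z.shape[0] == 1:
            me = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
        me = me / np.linalg.norm(me)
        mean_cor = np.mean([np.corrcoef(row, me)[0, 1] for row in z])
        if mean_cor < 0:
            me = -me
        out[mod] = me
    mes = pd.DataFrame(out, index=vals.columns).T
    mes.index.name = "module"
    return mes


def connectivity_stats(
    expr: ExpressionMatrix,
    adjacency: pd.DataFrame,
    modules: pd.Series,
    eigengenes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene module membership (kME) and intramodular connectivity.

    kME(g) = cor(x_g, ME of g's module); kWithin(g) = sum of adjacency to the
    other genes of g's module; ``kwithin_norm`` rescales kWithin to the module
    maximum so the hub threshold 0.5 is meaningful. Grey genes get NaN.
    """
    rows = []
    vals = expr.values
    for mod in [m for m in modules.unique() if m != GREY]:
        genes = modules.index[modules == mod]
        sub = vals.loc[genes].to_numpy(dtype=float)
        me = eigengenes.loc[mod].to_numpy(dtype=float)
        me_c = me - me.mean()
        sub_c = sub - sub.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(sub_c, axis=1) * np.linalg.norm(me_c)
        denom[denom == 0] = np.nan
        kme = sub_c @ me_c / denom
        a = adjacency.loc[genes, genes].to_numpy(dtype=float)
        kwithin = a.sum(axis=1) - np.diag(a)
        kmax = kwithin.max()
        rows.append(pd.DataFrame({
            "gene": genes,
            "module": mod,
            "kme": kme,
            "kwithin": kwithin,
            "kwithin_norm": kwithin / kmax if kmax > 0 else 0.0,
        }))
    grey_genes = modules.index[modules == GREY]
    if len(grey_genes):
        rows.append(pd.DataFrame({
            "gene": grey_genes, "module": GREY,
            "kme": np.nan, "kwithin": np.nan, "kwithin_norm": np.nan,
        }))
    table = pd.concat(rows, ignore_index=True).set_index("gene")
    return table.loc[modules.index]


def select_hubs(
    hub_table: pd.DataFrame,
    kme_min: float = 0.5,
    kwithin_min: float = 0.5,
    modules: Optional[Iterable[str]] = None,
) -> List[str]:
    """Hub genes: kME > kme_min AND normalized kWithin > kwithin_min (strict)."""
    tab = hub_table
    if modules is not None:
        tab = tab[tab["module"].isin(set(modules))]
    sel = (tab["kme"] > kme_min) & (tab["kwithin_norm"] > kwithin_min)
    return tab.index[sel.fillna(False)].tolist()


def ora_enrichment(
    query: Iterable[str],
    collection: Dict[str, Iterable[str]],
    universe: Iterable[str],
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a query list.

    For each set, the upper-tail probability of observing at least the actual
    overlap when drawing ``|query|`` genes from the universe; BH correction
    across the tested sets. Sets are restricted to their intersection with the
    universe and to sizes within ``[min_size, max_size]``.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in collection.items():
        members = set(genes) & universe
        if not members or not (min_size <= len(members) <= max_size):
            continue
        overlap = len(query & members)
        p = stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query))
        rows.append({"set": name, "set_size": len(members), "overlap": overlap, "p": float(p)})
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = []
    return table


def read_gmt(path) -> Dict[str, List[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
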