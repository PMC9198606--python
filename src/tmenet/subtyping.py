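"""Consensus clustering of bulk samples on TME marker-gene expression.

Samples are repeatedly subsampled and partitioned by Euclidean k-means on
gene-standardized expression; the co-clustering frequency matrix drives the
final partition (average-linkage clustering of 1 - consensus), the choice of k
(delta-area of the consensus CDF, unless pinned), and the per-sample
silhouette filter that discards ambiguously assigned samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


@dataclass
class ConsensusResult:
    """Output of :func:`consensus_cluster`."""

    consensus: Dict[int, pd.DataFrame]   # k -> sample x sample co-clustering frequency
    labels: Dict[int, pd.Series]         # k -> final sample labels (1..k)
    chosen_k: int
    silhouette: pd.Series                # per-sample width at chosen_k, on 1 - consensus
    cdf_area: Dict[int, float] = field(default_factory=dict)


def _standardize_genes(vals: pd.DataFrame) -> np.ndarray:
    arr = vals.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (arr - mu) / sd


def consensus_cluster(
    expr: ExpressionMatrix,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_resamples: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    fixed_k: Optional[int] = None,
) -> ConsensusResult:
    """Consensus k-means clustering of the matrix columns (samples).

    For each resample, ``subsample`` of the samples are drawn without
    replacement and clustered by k-means (k-means++ init, ``n_init`` restarts,
    Euclidean distance) on gene-standardized expression;
    ``consensus_ij = co-clustered / co-sampled``. Final labels come from
    average-linkage clustering of ``1 - consensus`` cut at k. ``chosen_k``
    maximizes the relative delta-area of the consensus CDF unless ``fixed_k``
    pins it.
    """
    n = expr.n_columns
    k_range = sorted(set(int(k) for k in k_range))
    if max(k_range) > n:
        raise ValueError(f"k={max(k_range)} exceeds the {n} available samples")
    if n < 2 * max(k_range):
        raise ValueError("need at least 2*max(k) samples for stable resampling")
    X = _standardize_genes(expr.values).T  # samples x genes
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))

    consensus: Dict[int, pd.DataFrame] = {}
    labels: Dict[int, pd.Series] = {}
    areas: Dict[int, float] = {}
    samples = expr.columns

    for k in k_range:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for b in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                        random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(X[idx])
            tog[np.ix_(idx, idx)] += 1.0
            same = lab[:, None] == lab[None, :]
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        cons_df = pd.DataFrame(cons, index=samples, columns=samples)
        consensus[k] = cons_df

        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        link = average(squareform(dist, checks=False))
        lab = fcluster(link, t=k, criterion="maxclust")
        labels[k] = pd.Series(lab, index=samples, name="tme_class")

        tri = cons[np.triu_indices(n, k=1)]
        grid = np.linspace(0.0, 1.0, 101)
        cdf = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        areas[k] = float(np.trapezoid(cdf, grid))

    if fixed_k is not None:
        chosen = int(fixed_k)
        if chosen not in consensus:
            raise ValueError(f"fixed_k={fixed_k} not in k_range {k_range}")
    else:
        ks = sorted(areas)
        delta = {ks[0]: areas[ks[0]]}
        for prev, k in zip(ks, ks[1:]):
            delta[k] = (areas[k] - areas[prev]) / areas[prev]
        chosen = max(delta, key=lambda k: delta[k])

    sil = _silhouette_widths(consensus[chosen], labels[chosen])
    return ConsensusResult(consensus=consensus, labels=labels, chosen_k=chosen,
                           silhouette=sil, cdf_area=areas)


def _silhouette_widths(consensus: pd.DataFrame, labels: pd.Series) -> pd.Series:
    dist = 1.0 - consensus.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    lab = labels.to_numpy()
    if len(np.unique(lab)) < 2:
        warnings.warn("single cluster: silhouette undefined, widths set to 0")
        widths = np.zeros(len(lab))
    else:
        widths = silhouette_samples(dist, lab, metric="precomputed")
    return pd.Series(widths, index=consensus.index, name="silhouette")


def silhouette_filter(
    consensus: pd.DataFrame, labels: pd.Series
) -> Tuple[pd.Index, pd.Series]:
    """Retain samples with silhouette width > 0 on the 1 - consensus distance.

    Samples in singleton clusters get width 0 and are dropped (with a
    warning). Returns (retained sample ids, all widths).
    """
    widths = _silhouette_widths(consensus, labels.loc[consensus.index])
    sizes = labels.value_counts()
    singletons = sizes[sizes == 1].index
    if len(singletons):
        warnings.warn(f"singleton cluster(s) {list(singletons)}: samples dropped")
    retained = widths.index[widths > 0]
    return retained, widths


def abundance_score(
    expr: ExpressionMatrix, marker_sets: Dict[str, Iterable[str]]
) -> pd.DataFrame:
    """Naive marker-mean abundance: per type, mean of z-scored marker genes.

    A coarse per-sample relative-abundance proxy (cell type x sample); types
    with no marker present in the matrix are skipped with a warning.
    """
    z = _standardize_genes(expr.values)
    zdf = pd.DataFrame(z, index=expr.genes, columns=expr.columns)
    rows = {}
    for ct, genes in marker_sets.items():
        present = [g for g in genes if g in zdf.index]
        if not present:
            warnings.warn(f"no markers of {ct!r} present; type skipped")
            continue
        rows[ct] = zdf.loc[present].mean(axis=0)
    table = pd.DataFrame(rows).T
    table.index.name = "cell_type"
    return table


def compare_classes(
    features: pd.DataFrame, classes: pd.Series
) -> pd.DataFrame:
    """Two-sided Welch t-test per feature (rows) between two classes (columns).

    Returns a table with t, p and BH q per feature. Features with zero
    variance in both groups get t = 0, p = 1 by convention.
    """
    classes = classes.loc[features.columns]
    levels = pd.unique(classes)
    if len(levels) != 2:
        raise ValueError(f"exactly two classes required, got {list(levels)}")
    a = features.loc[:, classes == levels[0]].to_numpy(dtype=float)
    b = features.loc[:, classes == levels[1]].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each class needs at least two samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=features.index)
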