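"""Single-cell QC, normalization and cell-component marker selection.

Markers are ranked per annotated cell type with a pooled two-sided Wilcoxon
rank-sum test (type vs. all other cells) on log2(TPM+1) values, with fold
change computed on the TPM scale. Cell component marker genes (CCMGs) are the
genes passing FC > 2 and p < 0.05 in exactly one type; the TME marker genes
(MEMGs) are the CCMGs whose identity is a microenvironmental type (B,
cytotoxic/T, myeloid, endothelial, fibroblast).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MEMG_TYPES, ExpressionMatrix


def qc_filter_cells(counts: ExpressionMatrix, nmads: float = 3.0) -> ExpressionMatrix:
    """Drop low-quality cells by library-size / detected-gene outlier tests.

    A cell is removed when its log library size or its log detected-gene count
    lies more than ``nmads`` (scaled) median absolute deviations *below* the
    respective median — the standard lower-tail QC outlier rule.
    """
    if counts.scale != "counts":
        raise ValueError("qc_filter_cells expects a counts-scale matrix")
    vals = counts.values.to_numpy()
    lib = vals.sum(axis=0)
    detected = (vals > 0).sum(axis=0)
    keep = np.ones(counts.n_columns, dtype=bool)
    for metric in (np.log1p(lib), np.log1p(detected)):
        med = np.median(metric)
        mad = stats.median_abs_deviation(metric, scale="normal")
        keep &= metric >= med - nmads * mad
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    return counts.subset_columns(counts.columns[keep])


def log_tpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert counts to log2(TPM+1): per column, TPM_g = count_g / total * 1e6."""
    if counts.scale != "counts":
        raise ValueError("log_tpm_normalize expects a counts-scale matrix")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total column(s): {list(zero.index[:5])}")
    tpm = counts.values / totals * 1e6
    return ExpressionMatrix(np.log2(tpm + 1.0), "log2tpm1")


def _wilcoxon_by_type(expr_vals: np.ndarray, in_type: np.ndarray):
    """Two-sided Mann-Whitney (U statistic, p) per gene, cells-of-type vs. rest."""
    res = stats.mannwhitneyu(
        expr_vals[:, in_type], expr_vals[:, ~in_type], axis=1, alternative="two-sided"
    )
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


def rank_markers(
    expr: ExpressionMatrix,
    ann: pd.DataFrame,
    min_cells: int = 3,
    pseudocount: float = 1.0,
    conserved_by_sample: bool = False,
) -> pd.DataFrame:
    """Rank per-cell-type markers against all remaining cells.

    Returns a table with one row per (gene, cell_type): ``fc`` (ratio of mean
    TPM + pseudocount in the type over the rest), ``p`` (two-sided Wilcoxon
    rank-sum) and ``padj`` (Benjamini-Hochberg within each type).

    With ``conserved_by_sample=True``, the test is run separately within each
    sample of origin and combined conservatively (max p across samples, min
    fold change), mirroring conserved-marker testing across datasets.
    """
    if expr.scale != "log2tpm1":
        raise ValueError("rank_markers expects log2(TPM+1) values")
    types = ann.loc[expr.columns, "cell_type"]
    counts_by_type = types.value_counts()
    usable = [t for t in counts_by_type.index if counts_by_type[t] >= min_cells]
    skipped = sorted(set(counts_by_type.index) - set(usable))
    if skipped:
        warnings.warn(f"cell types with < {min_cells} cells skipped: {skipped}")
    if len(usable) < 2:
        raise ValueError("need at least two cell types with enough cells")

    log_vals = expr.values.to_numpy()
    tpm = np.exp2(log_vals) - 1.0
    samples = ann.loc[expr.columns, "sample"].to_numpy()
    rows = []
    for ct in usable:
        in_type = (types == ct).to_numpy()
        mean_in = tpm[:, in_type].mean(axis=1)
        mean_out = tpm[:, ~in_type].mean(axis=1)
        fc = (mean_in + pseudocount) / (mean_out + pseudocount)
        if not conserved_by_sample:
            u, p = _wilcoxon_by_type(log_vals, in_type)
        else:
            p_parts, fc_parts, u_parts = [], [], []
            for s in np.unique(samples):
                sel = samples == s
                if in_type[sel].sum() >= min_cells and (~in_type[sel]).sum() >= min_cells:
                    u_s, p_s = _wilcoxon_by_type(log_vals[:, sel], in_type[sel])
                    p_parts.append(p_s)
                    u_parts.append(u_s)
                    m_in = tpm[:, sel][:, in_type[sel]].mean(axis=1)
                    m_out = tpm[:, sel][:, ~in_type[sel]].mean(axis=1)
                    fc_parts.append((m_in + pseudocount) / (m_out + pseudocount))
            if not p_parts:
                warnings.warn(f"no sample has enough {ct} cells for conserved testing")
                continue
            p = np.max(p_parts, axis=0)
            fc = np.min(fc_parts, axis=0)
            u = np.mean(u_parts, axis=0)
        padj = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "gene": expr.genes,
            "cell_type": ct,
            "fc": fc,
            "u": u,
            "p": p,
            "padj": padj,
        }))
    return pd.concat(rows, ignore_index=True)


def select_ccmgs(
    markers: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Select cell component marker genes: FC > fc_min, p < p_max, exclusive.

    Genes qualifying in two or more cell types are excluded outright; each
    remaining gene carries a unique cell-type identity. Thresholds are strict
    inequalities. Returns a catalog indexed by gene with columns
    ``identity, fc, p, padj, memg`` (MEMG = identity in the TME types).
    """
    pcol = "padj" if use_adjusted else "p"
    hits = markers[(markers["fc"] > fc_min) & (markers[pcol] < p_max)]
    n_ids = hits.groupby("gene")["cell_type"].nunique()
    exclusive = n_ids[n_ids == 1].index
    cat = (
        hits[hits["gene"].isin(exclusive)]
        .set_index("gene")
        .rename(columns={"cell_type": "identity"})
        .loc[:, ["identity", "fc", "p", "padj"]]
        .sort_index()
    )
    cat["memg"] = cat["identity"].isin(MEMG_TYPES)
    if cat.empty:
        warnings.warn("no gene passed the CCMG filters; catalog is empty")
    return cat


def select_memgs(ccmg: pd.DataFrame) -> pd.DataFrame:
    """Subset of the CCMG catalog representing microenvironmental cell types."""
    return ccmg[ccmg["identity"].isin(MEMG_TYPES)]


def write_catalog(ccmg: pd.DataFrame, path) -> None:
    ccmg.to_csv(path, sep="\t", index_label="gene")


def read_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", index_col="gene")
    cat["memg"] = cat["memg"].astype(bool)
    return cat
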