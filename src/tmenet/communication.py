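"""Ligand-receptor cell-cell communication scoring.

Single-cell edge weights follow the mean-expression convention: for each
(sender, target) cell-type pair and ligand-receptor pair, the edge weight is
the product of the ligand's mean TPM over sender cells and the receptor's mean
TPM over target cells. The bulk communication score is the geometric mean of
the ligand and receptor TPM, each normalized by the reference gene of its
assigned cell type, which lets the single-cell-derived connections be scored
per bulk sample and linked to outcome by Cox regression.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, to_tpm
from .simulate import REFERENCE_GENES  # canonical per-type reference genes
from .survival import fit_cox_univariate

LR_COLUMNS = ("ligand", "receptor")


def read_lr_pairs(path) -> pd.DataFrame:
    """Read a ligand-receptor pair CSV (connectomeDB-style column names OK)."""
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        lc = col.strip().lower()
        if lc.startswith("ligand"):
            rename[col] = "ligand"
        elif lc.startswith("receptor"):
            rename[col] = "receptor"
    df = df.rename(columns=rename)
    if not set(LR_COLUMNS) <= set(df.columns):
        raise ValueError("LR table needs ligand and receptor columns")
    df = df.drop_duplicates(subset=list(LR_COLUMNS)).reset_index(drop=True)
    if df[list(LR_COLUMNS)].isin(["", None]).any().any():
        raise ValueError("empty gene identifiers in LR table")
    return df


def demo_lr_pairs() -> pd.DataFrame:
    """Bundled demo ligand-receptor table (integrin/ECM junction pairs)."""
    with resources.as_file(resources.files("tmenet.data") / "lr_pairs_demo.csv") as p:
        return read_lr_pairs(p)


def demo_junction_genes() -> List[str]:
    """Bundled demo cell-junction annotation gene set."""
    from .coexpression import read_gmt

    with resources.as_file(resources.files("tmenet.data") / "gene_sets_demo.gmt") as p:
        sets = read_gmt(p)
    return sets["CELL_JUNCTION_ORGANIZATION"]


def filter_hub_junction_pairs(
    lr: pd.DataFrame, hub_genes: Iterable[str], junction_genes: Iterable[str]
) -> pd.DataFrame:
    """Restrict LR pairs to those touching a hub gene with junction annotation."""
    hub_junction = set(hub_genes) & set(junction_genes)
    keep = lr["ligand"].isin(hub_junction) | lr["receptor"].isin(hub_junction)
    out = lr[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("no LR pair touches a junction-annotated hub gene")
    return out


def sc_edge_weights(
    expr: ExpressionMatrix, ann: pd.DataFrame, lr: pd.DataFrame
) -> pd.DataFrame:
    """Mean-expression communication edges for every ordered cell-type pair.

    weight(sender, ligand, receptor, target) =
    mean(ligand TPM | sender cells) * mean(receptor TPM | target cells).
    Self-pairs are included; LR pairs missing from the matrix are skipped with
    a warning.
    """
    tpm = to_tpm(expr)
    types = ann.loc[tpm.columns, "cell_type"]
    type_means = tpm.values.T.groupby(types).mean().T  # gene x type
    cell_types = sorted(type_means.columns)

    rows = []
    for _, pair in lr.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in type_means.index or rec not in type_means.index:
            warnings.warn(f"LR pair ({lig}, {rec}) absent from the matrix; skipped")
            continue
        lm = type_means.loc[lig]
        rm = type_means.loc[rec]
        for sender in cell_types:
            for target in cell_types:
                rows.append({
                    "sender": sender, "ligand": lig,
                    "receptor": rec, "target": target,
                    "weight": float(lm[sender] * rm[target]),
                })
    return pd.DataFrame(rows, columns=["sender", "ligand", "receptor", "target", "weight"])


def top_connections(edges: pd.DataFrame) -> pd.DataFrame:
    """Best (sender, target) per LR pair by edge weight.

    Exact ties break lexicographically on (sender, target); LR pairs whose
    edges are all zero are reported with ``no_connection=True``.
    """
    ordered = edges.sort_values(
        ["ligand", "receptor", "weight", "sender", "target"],
        ascending=[True, True, False, True, True],
        kind="stable",
    )
    top = ordered.groupby(["ligand", "receptor"], sort=True).head(1).copy()
    top["no_connection"] = top["weight"] <= 0
    return top.reset_index(drop=True)


def bulk_comm_score(
    expr: ExpressionMatrix,
    ligand: str,
    receptor: str,
    sender: str,
    target: str,
    refs: Optional[Dict[str, str]] = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample bulk communication score for one directed LR connection.

    ``sqrt(((L + pc) / (Lref + pc)) * ((R + pc) / (Rref + pc)))`` where the
    ligand reference gene belongs to the sender type and the receptor reference
    to the target type. ``pseudocount=0`` reproduces the plain ratio form
    (exactly scale-equivariant); the default 1 guards zero reference TPM.
    """
    refs = refs or REFERENCE_GENES
    tpm = to_tpm(expr).values
    for role, ct in (("sender", sender), ("target", target)):
        if ct not in refs:
            raise ValueError(f"no reference gene declared for {role} cell type {ct!r}")
        if refs[ct] not in tpm.index:
            raise ValueError(f"reference gene {refs[ct]!r} of {role} type {ct!r} "
                             "missing from the matrix")
    for g in (ligand, receptor):
        if g not in tpm.index:
            raise ValueError(f"gene {g!r} missing from the matrix")
    L = tpm.loc[ligand].to_numpy(dtype=float)
    R = tpm.loc[receptor].to_numpy(dtype=float)
    Lref = tpm.loc[refs[sender]].to_numpy(dtype=float)
    Rref = tpm.loc[refs[target]].to_numpy(dtype=float)
    score = np.sqrt(((L + pseudocount) / (Lref + pseudocount))
                    * ((R + pseudocount) / (Rref + pseudocount)))
    return pd.Series(score, index=tpm.columns,
                     name=f"{sender}:{ligand}->{receptor}:{target}")


def comm_network_integrate(
    connections: pd.DataFrame,
    cohorts: Dict[str, Tuple[ExpressionMatrix, pd.DataFrame]],
    refs: Optional[Dict[str, str]] = None,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox-weight each top connection across bulk cohorts with survival.

    Per cohort, a univariate Cox fit on the standardized log communication
    score; the integrated HR is the geometric mean of per-cohort HRs, and an
    edge is flagged significant when HR > 1 with p < alpha in every cohort.
    Cohorts without events are skipped with a warning.
    """
    usable = {}
    for name, (expr, surv) in cohorts.items():
        if surv["event"].sum() == 0:
            warnings.warn(f"cohort {name!r} has no events; skipped")
            continue
        usable[name] = (expr, surv)
    if not usable:
        raise ValueError("no cohort with events")

    rows = []
    for _, edge in connections.iterrows():
        if edge.get("no_connection", False):
            continue
        rec = {k: edge[k] for k in ("sender", "ligand", "receptor", "target")}
        log_hrs, all_signif = [], True
        for name, (expr, surv) in usable.items():
            score = bulk_comm_score(expr, edge["ligand"], edge["receptor"],
                                    edge["sender"], edge["target"],
                                    refs=refs, pseudocount=pseudocount)
            x = np.log(score.loc[surv.index].to_numpy(dtype=float))
            sd = x.std()
            if sd == 0:
                all_signif = False
                continue
            fit = fit_cox_univariate((x - x.mean()) / sd, surv)
            rec[f"hr_{name}"] = fit.hr
            rec[f"p_{name}"] = fit.p
            log_hrs.append(fit.beta)
            all_signif &= (fit.hr > 1) and (fit.p < alpha)
        if not log_hrs:
            continue
        rec["integrated_hr"] = float(np.exp(np.mean(log_hrs)))
        rec["significant_all_cohorts"] = bool(all_signif)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("integrated_hr", ascending=False).reset_index(drop=True)
    return out


def alluvial_weights(
    connections: pd.DataFrame, expr: ExpressionMatrix, ann: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.Series]:
    """Molecule and cell-type weights for the sender-ligand-receptor-target flow.

    Each molecule is weighted by its mean TPM in its assigned cell type (the
    ligand in the sender, the receptor in the target of its top connection);
    each cell type is weighted by the sum of its contributing molecules.
    """
    tpm = to_tpm(expr)
    types = ann.loc[tpm.columns, "cell_type"]
    type_means = tpm.values.T.groupby(types).mean().T

    rows = []
    for _, edge in connections.iterrows():
        if edge.get("no_connection", False):
            continue
        rows.append({"molecule": edge["ligand"], "cell_type": edge["sender"],
                     "role": "ligand",
                     "weight": float(type_means.loc[edge["ligand"], edge["sender"]])})
        rows.append({"molecule": edge["receptor"], "cell_type": edge["target"],
                     "role": "receptor",
                     "weight": float(type_means.loc[edge["receptor"], edge["target"]])})
    mol = pd.DataFrame(rows, columns=["molecule", "cell_type", "role", "weight"])
    mol = mol.drop_duplicates(subset=["molecule", "cell_type", "role"]).reset_index(drop=True)
    cell = mol.groupby("cell_type")["weight"].sum()
    return mol, cell
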