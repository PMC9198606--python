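"""Shared data containers.

Every stage of the pipeline moves expression data around as a gene-by-column
matrix (columns are cells for single-cell data, samples for bulk data) with an
explicit scale tag, so that a matrix of raw counts can never be silently fed
into an operation expecting log2(TPM+1) values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: Valid scale tags, in the order transformations usually apply them.
SCALES = ("counts", "tpm", "log2tpm1")

#: The eight annotated cell components of the pancreatic tumor ecosystem.
CELL_TYPES = (
    "tumor",
    "fibroblast",
    "endothelial",
    "myeloid",
    "B",
    "cytotoxic",
    "acinar",
    "islet",
)

#: Microenvironmental (non-epithelial, non-exocrine/endocrine) cell types whose
#: exclusive markers constitute the TME marker-gene (MEMG) catalog.
MEMG_TYPES = frozenset({"B", "cytotoxic", "myeloid", "endothelial", "fibroblast"})


@dataclass
class ExpressionMatrix:
    """Gene x column expression matrix with named axes and a scale tag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers on the index and cell/sample
        identifiers on the columns.
    scale
        One of ``"counts"``, ``"tpm"`` or ``"log2tpm1"``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate column identifiers: {dups[:5]}")
        if self.scale in ("counts", "tpm"):
            arr = self.values.to_numpy()
            if np.isfinite(arr).all() and (arr < 0).any():
                raise ValueError(f"negative values on {self.scale} scale")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[genes])

    def subset_columns(self, columns: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(columns)])

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


def make_annotation(cell_ids, cell_types, samples=None) -> pd.DataFrame:
    """Build a cell annotation table (index: cell id; columns: cell_type, sample)."""
    ann = pd.DataFrame(
        {
            "cell_type": pd.Series(list(cell_types), index=list(cell_ids)),
            "sample": pd.Series(
                list(samples) if samples is not None else ["S0"] * len(list(cell_ids)),
                index=list(cell_ids),
            ),
        }
    )
    ann.index.name = "cell"
    return ann


def check_annotation(expr: ExpressionMatrix, ann: pd.DataFrame,
                     vocabulary: Iterable[str] = CELL_TYPES) -> None:
    """Validate that every matrix column is annotated with a known cell type."""
    missing = expr.columns.difference(ann.index)
    if len(missing):
        raise ValueError(f"{len(missing)} cells lack annotation (e.g. {list(missing[:3])})")
    unknown = set(ann.loc[expr.columns, "cell_type"]) - set(vocabulary)
    if unknown:
        raise ValueError(f"cell types outside declared vocabulary: {sorted(unknown)}")


def to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix on TPM scale (inverting log2(TPM+1) if needed)."""
    if expr.scale == "tpm":
        return expr
    if expr.scale == "log2tpm1":
        vals = np.exp2(expr.values) - 1.0
        return ExpressionMatrix(vals.clip(lower=0.0), "tpm")
    raise ValueError("counts must be normalized with log_tpm_normalize first")
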