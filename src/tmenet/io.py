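"""File input/output for the standard exchange formats.

Single-cell counts travel as MatrixMarket MTX plus features/barcodes TSV
(10x-style layout); bulk matrices as gene x sample TSV; survival as CSV;
truth, models and manifests as JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .containers import ExpressionMatrix


def write_mtx(expr: ExpressionMatrix, out_dir, prefix: str = "") -> None:
    """Write counts as <prefix>matrix.mtx + features.tsv + barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(expr.values.to_numpy())
    scio.mmwrite(out / f"{prefix}matrix.mtx", mat)
    pd.Series(expr.genes).to_csv(out / f"{prefix}features.tsv",
                                 sep="\t", index=False, header=False)
    pd.Series(expr.columns).to_csv(out / f"{prefix}barcodes.tsv",
                                   sep="\t", index=False, header=False)


def read_mtx(in_dir, prefix: str = "", scale: str = "counts") -> ExpressionMatrix:
    """Read a matrix written by :func:`write_mtx`."""
    p = Path(in_dir)
    mat = scio.mmread(p / f"{prefix}matrix.mtx")
    genes = pd.read_csv(p / f"{prefix}features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(p / f"{prefix}barcodes.tsv", sep="\t", header=None)[0]
    df = pd.DataFrame(np.asarray(mat.todense()), index=genes, columns=cells)
    df.index.name = None
    return ExpressionMatrix(df, scale)


def write_bulk_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_bulk_tsv(path, scale: str = "tpm") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index.name = None
    return ExpressionMatrix(df, scale)


def write_survival_csv(surv: pd.DataFrame, path) -> None:
    surv[["time", "event"]].to_csv(path, index_label="sample")


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="cell")


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell")
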