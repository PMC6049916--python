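"""Reading and writing the tabular formats the CLI exchanges."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from blendr.core import ExpressionMatrix
from blendr.errors import InputError, SchemaError


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_expression(path: str | Path, annot: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression table (first column row id, remaining samples).

    If the table carries an inline ``gene_symbol`` column it is used as the
    annotation; otherwise ``annot`` may point to a two-column row-id ->
    gene-symbol table.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise InputError(f"expression table {path} has no rows")
    symbols = None
    if "gene_symbol" in df.columns:
        symbols = df.pop("gene_symbol").astype(str)
    elif annot is not None:
        ann = pd.read_csv(annot, sep=_sep_for(annot), index_col=0)
        if ann.shape[1] < 1:
            raise SchemaError(f"annotation table {annot} needs a gene_symbol column")
        col = "gene_symbol" if "gene_symbol" in ann.columns else ann.columns[0]
        symbols = ann[col].astype(str)
    return ExpressionMatrix(values=df.astype(float), gene_symbols=symbols)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "row_id"
    df.to_csv(path, sep=_sep_for(path))


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (first column = sample id)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise InputError(f"covariate table {path} has no rows")
    return df


def read_indices(path: str | Path) -> pd.DataFrame:
    """Read a previously written index table (rows samples, columns indices)."""
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)
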