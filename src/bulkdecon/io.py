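"""Reading, validating and collapsing expression tables.

Expression tables are rectangular TSV/CSV files with genes in rows and
samples (or cell types) in columns; the first column holds gene identifiers
and the header row holds sample identifiers.  In memory every matrix is a
:class:`pandas.DataFrame` with gene ids on the index and sample/cell-type
labels on the columns.

The reference profile ``X`` used throughout the pipeline is obtained by
averaging the replicate columns of each FACS-purified cell type, giving a
g x k matrix with one column per cell type (columns in sorted label order).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "load_sample_sheet",
    "validate_expression",
    "collapse_replicates",
    "drop_silent_genes",
    "write_table",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def load_expression(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Load a genes x samples expression table.

    Parameters
    ----------
    path
        TSV/CSV file; first column = gene ids, header = sample ids.
    delimiter
        Explicit field separator.  When ``None`` it is inferred from the
        file extension (``.csv`` -> comma, anything else -> tab).

    Returns
    -------
    pandas.DataFrame
        Validated non-negative matrix.  Rows with missing values are
        dropped (logged); duplicate gene ids are resolved by keeping the
        row with the highest mean expression (logged).
    """
    sep = _detect_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValidationError(f"could not parse expression table {path!r}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"expression table {path!r} has no sample columns")
    df = df.apply(pd.to_numeric, errors="coerce")

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d rows with missing values", n_missing)
        df = df.dropna(axis=0)

    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "resolving %d duplicated gene ids by keeping the highest-mean row", n_dup
        )
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index()

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    """Check the ExpressionMatrix invariants (non-negative, unique labels)."""
    if df.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    if (df.to_numpy() < 0).any():
        raise ValidationError("expression matrix contains negative values")
    if df.index.has_duplicates:
        raise ValidationError("duplicate gene identifiers")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate sample identifiers")


def load_sample_sheet(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Load a two-column sample -> cell-type mapping.

    The file must have a header; the first column is the sample id and the
    second the cell-type label.
    """
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("sample sheet needs at least two columns (sample, cell_type)")
    sheet = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    if sheet.index.has_duplicates:
        raise ValidationError("sample sheet maps a sample to more than one cell type")
    return sheet


def collapse_replicates(expr: pd.DataFrame, sheet: pd.Series) -> pd.DataFrame:
    """Average replicate columns per cell type into the reference profile X.

    ``X[i, j]`` is the arithmetic mean over the purified samples of cell
    type ``j``.  Columns are ordered by sorted cell-type label so the
    output is invariant to the sample column order of ``expr``.
    """
    unmapped = [s for s in expr.columns if s not in sheet.index]
    if unmapped:
        raise ValidationError(f"samples not present in the sample sheet: {unmapped}")
    groups = sheet.reindex(expr.columns)
    X = expr.T.groupby(groups.to_numpy()).mean().T
    X = X[sorted(X.columns)]
    if X.shape[1] < 2:
        raise ValidationError("reference profile needs at least two cell types")
    return X


def drop_silent_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero expression everywhere (no specificity signal)."""
    keep = df.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d genes with zero expression in all columns", n_dropped)
    return df.loc[keep]


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Write a matrix in the TSV dialect the pipeline reads back."""
    df.to_csv(path, sep="\t", index_label=index_label)
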