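"""Delimited-table input/output for feature matrices and outcomes."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureMatrix, Outcome

__all__ = ["read_table", "write_table", "load_feature_matrix", "load_outcome"]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited table with a header row; strict numeric coercion.

    Raises with the offending location on ragged rows, duplicate column
    names or non-numeric cells.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0, index_col=None)
    dup = df.columns[df.columns.duplicated()].tolist()
    # pandas mangles duplicates to name.1; detect the originals too
    raw_header = open(path).readline().rstrip("\n").split(sep)
    seen, raw_dup = set(), []
    for name in raw_header:
        if name in seen:
            raw_dup.append(name)
        seen.add(name)
    if dup or raw_dup:
        raise ValueError(f"duplicate column names: {sorted(set(dup) | set(raw_dup))}")
    first = df.columns[0]
    index_like = df[first].dtype == object
    for col in df.columns:
        if index_like and col == first:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {col!r}, row {int(bad[0]) + 2} "
                f"(value {df.loc[bad[0], col]!r})"
            )
        df[col] = coerced
    if index_like:
        df = df.set_index(first)
    return df


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index=df.index.name is not None)


def load_feature_matrix(
    path: str | Path,
    delimiter: str | None = None,
    features_as_rows: bool = False,
    drop_columns: tuple[str, ...] = (),
) -> FeatureMatrix:
    """Load an n×p predictor table (or its transpose with features_as_rows)."""
    df = read_table(path, delimiter)
    if features_as_rows:
        df = df.T
    df = df.drop(columns=[c for c in drop_columns if c in df.columns])
    sample_ids = [str(i) for i in df.index] if df.index.name is not None else None
    return FeatureMatrix(df.to_numpy(float), [str(c) for c in df.columns], sample_ids)


def load_outcome(
    path_or_df: str | Path | pd.DataFrame,
    column: str | None = None,
    kind: str = "continuous",
    delimiter: str | None = None,
) -> Outcome:
    """Outcome from a named column of a table, or a single-column file."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = read_table(path_or_df, delimiter)
    if column is None:
        if df.shape[1] != 1:
            raise ValueError("outcome file must have exactly one column, or name one")
        column = df.columns[0]
    if column not in df.columns:
        raise ValueError(f"outcome column {column!r} not found")
    return Outcome(df[column].to_numpy(float), kind=kind)
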