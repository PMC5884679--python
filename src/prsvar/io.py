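"""Readers and writers for the canonical per-cell table.

The interchange format is plain delimited text (CSV or TSV) with one row
per cell.  Required columns: ``strain, dose_nM, replicate, ind_r, con_y``;
optional: ``time_min, ind_c, cell_id``.  Fluorescence values are arbitrary
units, doses are nM, times are minutes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["read_cell_table", "write_cell_table", "validate_cell_table"]

logger = logging.getLogger("prsvar")

REQUIRED_COLUMNS = ("strain", "dose_nM", "replicate", "ind_r", "con_y")
OPTIONAL_NUMERIC = ("time_min", "ind_c", "cell_id")
NUMERIC_COLUMNS = ("dose_nM", "ind_r", "con_y", "time_min", "ind_c")
NONNEGATIVE_COLUMNS = ("dose_nM", "ind_r", "con_y", "time_min", "ind_c")


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    if fmt not in ("csv", "tsv"):
        raise SchemaError(f"unknown format {fmt!r}; use 'csv' or 'tsv'")
    return "\t" if fmt == "tsv" else ","


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-validate a per-cell table; returns the coerced table."""
    if df.empty:
        raise SchemaError("empty cell table")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"non-numeric value in column '{col}' at row {row}: {df[col].iloc[row]!r}"
            )
        if coerced.isna().any() and col in REQUIRED_COLUMNS:
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SchemaError(f"missing value in required column '{col}' at row {row}")
        df[col] = coerced
    for col in NONNEGATIVE_COLUMNS:
        if col in df.columns and (df[col] < 0).any():
            row = int(np.flatnonzero((df[col] < 0).to_numpy())[0])
            raise SchemaError(f"negative value in column '{col}' at row {row}")
    for col in ("ind_r", "con_y", "ind_c"):
        if col in df.columns and not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise SchemaError(f"non-finite value in column '{col}'")
    return df


def read_cell_table(path, fmt: str | None = None) -> pd.DataFrame:
    """Read and schema-validate a per-cell table (csv or tsv).

    Logs the row count and the per-population (strain x dose x replicate)
    cell counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path, fmt)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    df = validate_cell_table(df)
    logger.info("read %d cells from %s", len(df), path)
    counts = df.groupby(["strain", "dose_nM", "replicate"]).size()
    logger.info("populations: %d (min %d, max %d cells)", len(counts), counts.min(), counts.max())
    return df


def write_cell_table(df: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a per-cell table as delimited text at full precision."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    validate_cell_table(df)
    df.to_csv(path, sep=sep, index=False)
    logger.info("wrote %d cells to %s", len(df), path)
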