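"""Tabular input/output by file extension (CSV or Parquet)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    raise DataError(f"unsupported table format: {path.suffix!r} (use .csv or .parquet)")


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table; the format follows the extension. CSV output is
    byte-deterministic (fixed float formatting, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif path.suffix in (".parquet", ".pq"):
        df.to_parquet(path, index=False)
    else:
        raise DataError(f"unsupported table format: {path.suffix!r} (use .csv or .parquet)")
    return path
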