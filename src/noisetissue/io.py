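"""Reading and writing the package's CSV dialects.

The measurement dialect is one row per nucleus per channel per time point
per technical replicate:

    image_id, cell_id, tissue, x_um, y_um, area_um2,
    channel, time_h, replicate, mean_grey, background_mean_grey

Grey values are 8-bit mean grey (0-255). The reader validates the schema
(missing columns are named; non-numeric entries are reported with their
line number) and the writer round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .measurements import REQUIRED_COLUMNS, NucleusTable

__all__ = ["read_nucleus_table", "write_nucleus_table"]

_NUMERIC = ["x_um", "y_um", "area_um2", "time_h", "mean_grey", "background_mean_grey"]


def read_nucleus_table(path) -> NucleusTable:
    """Read and validate a raw measurement table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in _NUMERIC + ["replicate"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[bad, col].iloc[0]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = vals.astype(int) if col == "replicate" else vals
    if ((df["mean_grey"] < 0) | (df["mean_grey"] > 255)).any():
        raise SchemaError(f"{path}: mean_grey outside the 8-bit range [0, 255]")
    if (df["area_um2"] <= 0).any():
        raise SchemaError(f"{path}: non-positive nuclear area")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise SchemaError(f"{path}: non-finite nucleus position")
    return NucleusTable(df[REQUIRED_COLUMNS].reset_index(drop=True))


def write_nucleus_table(table: NucleusTable, path) -> None:
    """Write a measurement table; ``read_nucleus_table`` round-trips it."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data[REQUIRED_COLUMNS].to_csv(path, index=False)
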