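"""CSV dialect for record tables.

Mandatory columns ``cow_id, country, parity, wol, my, dmi, pbw, pfat,
pprot, plact`` followed by ``pfa_<name>`` columns and spectral columns
``wn_<wavenumber>`` (two decimals, cm^-1); UTF-8, period decimal
separator.  Files may open with ``#``-prefixed header comment lines (the
pipeline stamps the config hash and seed there); reading skips them."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .records import MANDATORY_COLUMNS, spectral_columns, validate_records


def read_records(path) -> pd.DataFrame:
    """Read a record table, validating the dialect.

    Missing mandatory columns raise naming the column; malformed numerics
    raise naming the column and offending row numbers; out-of-order
    spectral columns are reordered with a warning."""
    df = pd.read_csv(path, comment="#")
    validate_records(df)
    numeric = [c for c in df.columns if c not in ("cow_id", "country")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # 1-based + header
            raise ValueError(f"malformed numeric value(s) in column {col!r} "
                             f"at file row(s) {rows[:10]}")
        df[col] = converted
    spec = spectral_columns(df)
    in_file_order = [c for c in df.columns if c.startswith("wn_")]
    if spec != in_file_order:
        warnings.warn("spectral columns out of wavenumber order; reordering")
        other = [c for c in df.columns if not c.startswith("wn_")]
        df = df[other + spec]
    return df


def write_records(records: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a record table; optional ``header`` mapping becomes
    ``# key: value`` comment lines."""
    validate_records(records)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for key, value in header.items():
                fh.write(f"# {key}: {value}\n")
        records.to_csv(fh, index=False)
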