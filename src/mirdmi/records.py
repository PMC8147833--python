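"""Canonical test-day record table.

A cohort is a plain :class:`pandas.DataFrame` with one row per milk test-day.
Mandatory columns are ``cow_id``, ``country``, ``parity``, ``wol`` (week of
lactation), ``my`` (milk yield, kg/d), ``dmi`` (dry matter intake, kg/d),
``pbw`` (MIR-predicted bodyweight, kg) and the MIR-predicted milk composition
``pfat``/``pprot``/``plact`` (g/dL).  Predicted fatty-acid contents live in
``pfa_<slug>`` columns (g/dL) and spectral absorbances (log 1/T) in
``wn_<wavenumber>`` columns, one per grid point, two-decimal wavenumber in
cm^-1.  An optional ``month`` column carries the calendar test month.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = [
    "cow_id",
    "country",
    "parity",
    "wol",
    "my",
    "dmi",
    "pbw",
    "pfat",
    "pprot",
    "plact",
]

SPECTRAL_PREFIX = "wn_"
FA_PREFIX = "pfa_"

_WN_RE = re.compile(r"^wn_(\d+(?:\.\d+)?)$")


def fa_slug(name: str) -> str:
    """Column name for a fatty acid, e.g. ``C18:1 cis-9`` -> ``pfa_c18_1_cis_9``."""
    slug = name.lower().replace(":", "_").replace(",", "_")
    slug = re.sub(r"[\s\-]+", "_", slug).strip("_")
    return FA_PREFIX + slug


def spectral_col(wavenumber: float) -> str:
    return f"{SPECTRAL_PREFIX}{wavenumber:.2f}"


def spectral_columns(df: pd.DataFrame) -> list[str]:
    """Spectral column names sorted by wavenumber."""
    cols = []
    for c in df.columns:
        m = _WN_RE.match(c)
        if m:
            cols.append((float(m.group(1)), c))
    cols.sort()
    return [c for _, c in cols]


def wavenumbers(df: pd.DataFrame) -> np.ndarray:
    """Wavenumber grid (cm^-1) implied by the spectral columns, ascending."""
    return np.array([float(_WN_RE.match(c).group(1)) for c in spectral_columns(df)])


def spectral_matrix(df: pd.DataFrame) -> np.ndarray:
    """n x p absorbance matrix, columns in ascending wavenumber order."""
    cols = spectral_columns(df)
    if not cols:
        raise ValueError("record table has no spectral (wn_*) columns")
    return df[cols].to_numpy(dtype=float)


def fa_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(FA_PREFIX)]


def validate_records(df: pd.DataFrame) -> None:
    """Raise ``ValueError`` naming any missing mandatory column."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
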