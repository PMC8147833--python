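"""Spectral harmonization, window selection and outlier filtering.

Spectra from different instruments are linearly interpolated onto a common
wavenumber grid, restricted to the informative windows (water regions
excluded), and screened with the standardized global H distance (GH):
the squared Mahalanobis distance of each spectrum in principal-component
score space, divided by the number of components retained to explain a
given fraction of the spectral variance.  Records with GH above a
threshold (default 5) are treated as spectral outliers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .records import spectral_columns, spectral_matrix

#: Default common grid of the harmonized spectra.
N_POINTS = 797
GRID_MIN = 925.66
GRID_MAX = 3995.78

#: Informative wavenumber windows (cm^-1), open intervals: the milk
#: composition fingerprint, ester carbonyl and C-H stretch regions.
DEFAULT_WINDOWS = ((950.0, 1600.0), (1750.0, 1800.0), (2600.0, 3000.0))

#: Default record-level plausibility filters (kg/d).
DMI_MIN = 10.0
DMI_MAX = 34.0
MY_MIN = 10.0

GH_THRESHOLD = 5.0
VARIANCE_THRESHOLD = 0.99


def make_common_grid(n_points: int = N_POINTS, lo: float = GRID_MIN,
                     hi: float = GRID_MAX) -> np.ndarray:
    """Evenly spaced inclusive wavenumber grid."""
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    if not lo < hi:
        raise ValueError("degenerate grid bounds: lo must be < hi")
    return np.linspace(lo, hi, n_points)


def interpolate_spectrum(src_grid: np.ndarray, values: np.ndarray,
                         dst_grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of one spectrum (or a stack of spectra)
    onto ``dst_grid``.  No extrapolation: every destination point must lie
    within the closed span of the source grid."""
    src_grid = np.asarray(src_grid, dtype=float)
    dst_grid = np.asarray(dst_grid, dtype=float)
    if src_grid.ndim != 1 or len(src_grid) < 2:
        raise ValueError("source grid must be 1-D with length >= 2")
    if np.any(np.diff(src_grid) <= 0):
        raise ValueError("source grid must be strictly increasing")
    if dst_grid.min() < src_grid[0] or dst_grid.max() > src_grid[-1]:
        raise ValueError("destination grid outside source span (no extrapolation)")
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(dst_grid, src_grid, values)
    return np.vstack([np.interp(dst_grid, src_grid, row) for row in values])


def select_windows(grid: np.ndarray,
                   windows=DEFAULT_WINDOWS) -> np.ndarray:
    """Indices of grid points strictly inside any of the (open) windows."""
    grid = np.asarray(grid, dtype=float)
    win = sorted(tuple(w) for w in windows)
    for lo, hi in win:
        if not lo < hi:
            raise ValueError(f"degenerate window ({lo}, {hi})")
    for (lo1, hi1), (lo2, hi2) in zip(win, win[1:]):
        if lo2 < hi1:
            raise ValueError("windows overlap")
    mask = np.zeros(len(grid), dtype=bool)
    for lo, hi in win:
        mask |= (grid > lo) & (grid < hi)
    return np.nonzero(mask)[0]


def filter_records(records: pd.DataFrame, dmi_min: float = DMI_MIN,
                   dmi_max: float = DMI_MAX, my_min: float = MY_MIN):
    """Drop implausible records.  Kept iff dmi_min <= DMI <= dmi_max and
    MY >= my_min (boundary values kept).  Returns ``(kept, dropped)``."""
    if not np.isfinite([dmi_min, dmi_max, my_min]).all():
        raise ValueError("thresholds must be finite")
    if not dmi_min < dmi_max:
        raise ValueError("dmi_min must be < dmi_max")
    if len(records) == 0:
        return records.copy(), records.copy()
    ok = (
        (records["dmi"] >= dmi_min)
        & (records["dmi"] <= dmi_max)
        & (records["my"] >= my_min)
    )
    return records.loc[ok].copy(), records.loc[~ok].copy()


@dataclasses.dataclass
class GHReport:
    """Per-record spectral outlyingness.

    ``md2`` is the squared Mahalanobis distance in the space of the
    ``n_components`` retained principal components (scores standardized by
    their standard deviations); ``gh = md2 / n_components``.
    """

    md2: np.ndarray
    n_components: int
    gh: np.ndarray
    threshold: float | None = None
    keep: np.ndarray | None = None

    def to_frame(self, ids=None) -> pd.DataFrame:
        out = pd.DataFrame({
            "md2": self.md2,
            "n_pcs": self.n_components,
            "gh": self.gh,
        })
        if self.keep is not None:
            out["kept"] = self.keep
        if ids is not None:
            out.insert(0, "record_id", np.asarray(ids))
        return out


def compute_gh(spectra: np.ndarray, variance_threshold: float = VARIANCE_THRESHOLD,
               gh_threshold: float | None = None) -> GHReport:
    """Standardized global H distance of each spectrum.

    PCA on the centered (unscaled) spectra via SVD; the smallest number of
    components whose cumulative explained variance reaches
    ``variance_threshold`` is retained; each record's squared Mahalanobis
    distance is the sum of its squared SD-standardized scores, and GH is
    that distance divided by the component count.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 records")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = np.sum(s**2)
    if total <= 0:
        raise ValueError("zero-variance spectral matrix")
    explained = s**2 / total
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(s))
    # score t_ik = U_ik * s_k has SD s_k / sqrt(n-1); standardizing leaves
    # U_ik * sqrt(n-1), so md2_i = (n-1) * sum_k U_ik^2.
    md2 = (n - 1) * np.sum(U[:, :k] ** 2, axis=1)
    gh = md2 / k
    keep = gh <= gh_threshold if gh_threshold is not None else None
    return GHReport(md2=md2, n_components=k, gh=gh,
                    threshold=gh_threshold, keep=keep)


def gh_filter(records: pd.DataFrame, gh_threshold: float = GH_THRESHOLD,
              variance_threshold: float = VARIANCE_THRESHOLD,
              max_iter: int = 10):
    """Drop spectral outliers with GH above the threshold.

    The elimination is applied iteratively (the usual chemometric
    practice): records with GH above the threshold are removed, the PCA
    model and GH are recomputed on the remainder, and so on until no
    record exceeds the threshold or ``max_iter`` passes have run.  A
    single iteration is susceptible to masking — a block of gross
    outliers inflates the variance along its own direction and caps its
    own standardized distance — which the re-fit removes.  Iteration also
    makes the filter idempotent by construction.  Set ``max_iter=1`` for
    one plain pass.

    Returns ``(kept, dropped, report)``; the report rows align with the
    input records, carrying each record's GH from the pass on which it
    was last scored (the final pass for kept records, the pass of removal
    for dropped ones).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = len(records)
    gh = np.full(n, np.nan)
    md2 = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    n_components = 0
    for _ in range(max_iter):
        X = spectral_matrix(records.loc[active])
        rep = compute_gh(X, variance_threshold=variance_threshold,
                         gh_threshold=gh_threshold)
        idx = np.nonzero(active)[0]
        gh[idx] = rep.gh
        md2[idx] = rep.md2
        n_components = rep.n_components
        bad = idx[~rep.keep]
        if len(bad) == 0:
            break
        active[bad] = False
    report = GHReport(md2=md2, n_components=n_components, gh=gh,
                      threshold=gh_threshold, keep=active.copy())
    return records.loc[active].copy(), records.loc[~active].copy(), report


def standardize_spectra_hook(records: pd.DataFrame,
                             slope: np.ndarray | None = None,
                             offset: np.ndarray | None = None) -> pd.DataFrame:
    """Per-wavenumber affine spectral standardization hook.

    Applies ``new = slope * old + offset`` to every spectrum; identity by
    default.  Intended as the attachment point for instrument-to-instrument
    standardization (e.g. piecewise-direct or master-slave conversions),
    which is outside the scope of this package.
    """
    cols = spectral_columns(records)
    p = len(cols)
    out = records.copy()
    X = out[cols].to_numpy(dtype=float)
    if slope is not None:
        slope = np.asarray(slope, dtype=float)
        if slope.shape not in ((p,), ()):
            raise ValueError("slope dimension does not match the spectral grid")
        X = X * slope
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        if offset.shape not in ((p,), ()):
            raise ValueError("offset dimension does not match the spectral grid")
        X = X + offset
    out[cols] = X
    return out
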