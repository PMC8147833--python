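"""Design matrices for the M1-M22 model constructs.

Seven predictor groups are combined into 22 constructs: the windowed MIR
spectral points (MIR), parity encoded with orthogonal polynomial contrasts
(PRT), week of lactation encoded likewise over the observed training weeks
(WOL), milk yield (MY), MIR-predicted bodyweight (pBW), retained
fatty acids as proportions of milk fat (pFA) and MIR-predicted milk
composition fat/protein/lactose (pMC).

Ordinal encodings use discrete orthonormal polynomials, built once on the
calibration categories and evaluated *functionally* for new records, so an
out-of-range week at prediction time yields finite polynomial extrapolation
rather than an error.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .records import fa_slug, spectral_columns

GROUP_NAMES = ("MIR", "PRT", "WOL", "MY", "pBW", "pFA", "pMC")

#: Construct registry: id -> predictor groups, in naming order.
CONSTRUCTS: dict[str, tuple[str, ...]] = {
    "M1": ("MIR",),
    "M2": ("PRT",),
    "M3": ("pFA",),
    "M4": ("pBW",),
    "M5": ("MY",),
    "M6": ("WOL",),
    "M7": ("pMC",),
    "M8": ("PRT", "MIR"),
    "M9": ("pBW", "MIR"),
    "M10": ("MY", "MIR"),
    "M11": ("pFA", "MIR"),
    "M12": ("PRT", "MIR", "pBW"),            # M8 + pBW
    "M13": ("PRT", "MIR", "MY"),             # M8 + MY
    "M14": ("pBW", "MIR", "MY"),             # M9 + MY
    "M15": ("PRT", "MIR", "MY", "pBW"),      # M13 + pBW
    "M16": ("PRT", "MIR", "MY", "pBW", "WOL"),
    "M17": ("PRT", "MIR", "MY", "pBW", "pFA"),
    "M18": ("PRT", "MIR", "MY", "pBW", "pMC"),
    "M19": ("PRT", "MIR", "MY", "pBW", "WOL", "pFA"),
    "M20": ("PRT", "MIR", "MY", "pBW", "WOL", "pMC"),
    "M21": ("PRT", "MIR", "MY", "pBW", "pFA", "pMC"),
    "M22": ("PRT", "MIR", "MY", "pBW", "WOL", "pFA", "pMC"),
}

#: Fatty acids retained by VIP > 1 screening of the MIR-predicted FA panel.
RETAINED_FA = ("C8:0", "C10:0", "C12:0", "C14:0", "C18:0", "C18:1 cis-9")


def retained_fa_panel() -> list[str]:
    """Default fatty-acid panel entering the pFA group (overridable by a
    VIP-selection run)."""
    return list(RETAINED_FA)


class OrthogonalPolynomialBasis:
    """Discrete orthonormal polynomial contrasts over an ordered score set.

    At the ``k`` fitting scores the columns are exactly orthonormal,
    orthogonal to the constant vector, with column ``j`` a degree-``j``
    polynomial of the score (the classical ordinal contrast coding).  The
    basis is a *function* of the score: :meth:`evaluate` returns the same
    polynomials at arbitrary (possibly unseen) scores.
    """

    def __init__(self, scores):
        x = np.asarray(scores, dtype=float)
        if x.ndim != 1 or len(np.unique(x)) != len(x):
            raise ValueError("scores must be 1-D and distinct")
        if len(x) < 2:
            raise ValueError("need at least 2 categories")
        order = np.argsort(x)
        self.scores = x[order]
        k = len(self.scores)
        # scale to [-1, 1] for conditioning
        self._center = (self.scores[0] + self.scores[-1]) / 2.0
        self._half = (self.scores[-1] - self.scores[0]) / 2.0
        z = (self.scores - self._center) / self._half
        self._z = z
        # Gram-Schmidt on 1, z*p0, z*p1, ... with full (two-pass)
        # reorthogonalization.  The projection coefficients and norms are
        # stored so `evaluate` can replay the identical polynomial
        # construction at arbitrary scores; this stays orthonormal to
        # machine precision up to high degree, where a Vandermonde solve
        # would not.
        P = np.empty((k, k))
        P[:, 0] = 1.0 / np.sqrt(k)
        coeffs: list[list[np.ndarray]] = [[]]
        norms = [1.0]
        for j in range(1, k):
            q = z * P[:, j - 1]
            passes = []
            for _ in range(2):
                c = P[:, :j].T @ q
                q = q - P[:, :j] @ c
                passes.append(c)
            nrm = float(np.linalg.norm(q))
            if nrm == 0.0:
                raise ValueError("degenerate score set")
            P[:, j] = q / nrm
            coeffs.append(passes)
            norms.append(nrm)
        self._P = P
        self._coeffs = coeffs
        self._norms = norms

    @property
    def k(self) -> int:
        return len(self.scores)

    def contrasts(self) -> np.ndarray:
        """k x (k-1) contrast matrix at the fitting scores."""
        return self._P[:, 1:].copy()

    def evaluate(self, scores) -> np.ndarray:
        """Contrast values at arbitrary scores (n x (k-1)); polynomial
        extrapolation outside the fitted range."""
        zx = (np.atleast_1d(np.asarray(scores, dtype=float)) - self._center) / self._half
        n, k = len(zx), self.k
        V = np.empty((n, k))
        V[:, 0] = 1.0 / np.sqrt(k)
        for j in range(1, k):
            q = zx * V[:, j - 1]
            for c in self._coeffs[j]:
                q = q - V[:, :j] @ c
            V[:, j] = q / self._norms[j]
        return V[:, 1:]


def orthogonal_contrasts(k: int) -> np.ndarray:
    """Orthonormal polynomial contrasts for ``k`` ordered categories
    scored 1..k: a k x (k-1) matrix M with M'M = I and 1'M = 0."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return OrthogonalPolynomialBasis(np.arange(1, k + 1)).contrasts()


@dataclasses.dataclass
class FeatureMatrix:
    """Numeric design matrix with per-column feature-group tags."""

    ids: np.ndarray
    columns: list[str]
    groups: list[str]
    X: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.X.shape != (len(self.ids), len(self.columns)):
            raise ValueError("feature matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group],
                        dtype=int)


def parity_category(parity) -> np.ndarray:
    """Collapse raw parities to the three ordered levels 1 / 2 / 3+."""
    p = np.asarray(parity, dtype=int)
    if np.any(p < 1):
        raise ValueError("parity must be >= 1")
    return np.minimum(p, 3)


def fa_to_fat_proportion(fa, fat):
    """Fatty-acid content expressed as percent of milk fat: 100*fa/fat."""
    fa = np.asarray(fa, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if np.any(fat <= 0):
        raise ValueError("fat content must be > 0")
    if np.any(fa < 0):
        raise ValueError("fatty-acid content must be >= 0")
    return 100.0 * fa / fat


class ConstructEncoder:
    """Fit-on-calibration / transform-anywhere encoder for one construct.

    Fitting learns the observed week-of-lactation categories (hence the WOL
    contrast degree), the spectral columns present, and the fatty-acid
    panel; transforming evaluates the same encoding on any record table,
    including weeks never seen during fitting.
    """

    #: fixed parity category space: first / second / third-and-later
    _PARITY_SCORES = np.array([1.0, 2.0, 3.0])

    def __init__(self, construct, fa_panel=None):
        if isinstance(construct, str):
            if construct not in CONSTRUCTS:
                raise KeyError(f"unknown construct id: {construct!r}")
            self.construct_id = construct
            self.group_names = CONSTRUCTS[construct]
        else:
            self.construct_id = "+".join(construct)
            self.group_names = tuple(construct)
        unknown = set(self.group_names) - set(GROUP_NAMES)
        if unknown:
            raise KeyError(f"unknown feature group(s): {sorted(unknown)}")
        self.fa_panel = list(fa_panel) if fa_panel is not None else retained_fa_panel()
        self._fitted = False

    def fit(self, records: pd.DataFrame) -> "ConstructEncoder":
        self._parity_basis = OrthogonalPolynomialBasis(self._PARITY_SCORES)
        if "PRT" in self.group_names:
            cats = parity_category(records["parity"])
            if len(np.unique(cats)) < 2:
                warnings.warn("single parity category in calibration data; "
                              "PRT contrast columns are constant")
        if "WOL" in self.group_names:
            weeks = np.unique(np.asarray(records["wol"], dtype=float))
            if len(weeks) < 2:
                raise ValueError("need >= 2 distinct weeks of lactation to "
                                 "encode WOL")
            self._wol_basis = OrthogonalPolynomialBasis(weeks)
        if "MIR" in self.group_names:
            self._mir_cols = spectral_columns(records)
            if not self._mir_cols:
                raise ValueError("records carry no spectral columns")
        if "pFA" in self.group_names:
            missing = [n for n in self.fa_panel
                       if fa_slug(n) not in records.columns]
            if missing:
                raise ValueError(f"missing fatty-acid column(s): {missing}")
        self._fitted = True
        return self

    def _group(self, name: str, records: pd.DataFrame):
        if name == "MIR":
            return self._mir_cols, records[self._mir_cols].to_numpy(float)
        if name == "PRT":
            cats = parity_category(records["parity"])
            M = self._parity_basis.evaluate(cats.astype(float))
            return ["prt_L", "prt_Q"], M
        if name == "WOL":
            M = self._wol_basis.evaluate(np.asarray(records["wol"], float))
            cols = [f"wol_p{j}" for j in range(1, self._wol_basis.k)]
            return cols, M
        if name == "MY":
            return ["my"], records[["my"]].to_numpy(float)
        if name == "pBW":
            return ["pbw"], records[["pbw"]].to_numpy(float)
        if name == "pFA":
            cols = [fa_slug(n) + "_pct" for n in self.fa_panel]
            vals = np.column_stack([
                fa_to_fat_proportion(records[fa_slug(n)], records["pfat"])
                for n in self.fa_panel
            ])
            return cols, vals
        if name == "pMC":
            return ["pfat", "pprot", "plact"], records[["pfat", "pprot", "plact"]].to_numpy(float)
        raise KeyError(name)

    def transform(self, records: pd.DataFrame) -> FeatureMatrix:
        if not self._fitted:
            raise RuntimeError("encoder not fitted")
        columns, groups, blocks = [], [], []
        for name in self.group_names:
            cols, vals = self._group(name, records)
            columns.extend(cols)
            groups.extend([name] * len(cols))
            blocks.append(np.atleast_2d(vals))
        X = np.hstack(blocks)
        return FeatureMatrix(ids=records["cow_id"].to_numpy(), columns=columns,
                             groups=groups, X=X)


def build_construct(records: pd.DataFrame, construct,
                    fa_panel=None) -> FeatureMatrix:
    """Fit an encoder on ``records`` and return their design matrix."""
    return ConstructEncoder(construct, fa_panel=fa_panel).fit(records).transform(records)
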