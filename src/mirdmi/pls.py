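"""From-scratch PLS1 regression (NIPALS) with variance accounting and VIP.

The engine fits on column-centered, unscaled data (spectral channels share
units, so no unit-variance scaling).  For a univariate response the NIPALS
weight of each factor is exact in one pass: w_f = X'y / ||X'y||, the score
t_f = X w_f, X is deflated by its rank-one reconstruction t_f p_f', and y
is regressed on the score (y-loading q_f).  Regression coefficient vectors
are recoverable for every truncation a <= A via B_a = W_a (P_a' W_a)^-1 q_a,
which makes model-size searches cheap.

Variable Importance in Projection (VIP) follows the standard definition

    VIP_j = sqrt( p * sum_f SSY_f w_jf^2 / sum_f SSY_f ),

where SSY_f = q_f^2 t_f't_f is the y-variation captured by factor f; the
mean squared VIP equals 1, so VIP > 1 flags above-average predictors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .features import FeatureMatrix

MAX_FACTORS = 20  # default ceiling on the number of PLS components


@dataclasses.dataclass
class PLSFit:
    """Centered-data PLS1 model."""

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray          # p x A weight vectors (unit norm)
    P: np.ndarray          # p x A X-loadings
    q: np.ndarray          # A y-loadings
    t_ss: np.ndarray       # A score sums of squares t_f't_f
    x_var_explained: np.ndarray  # per-factor fraction of centered-X SS
    y_ss_explained: np.ndarray   # per-factor SSY_f
    columns: list[str] | None = None

    def __post_init__(self):
        self._coef_cache: dict[int, tuple[np.ndarray, float]] = {}
        # rotation R = W (P'W)^-1 maps centered X to scores directly
        A = self.W.shape[1]
        if A:
            PtW = self.P.T @ self.W
            self._rotation = self.W @ np.linalg.solve(PtW, np.eye(A))
        else:
            self._rotation = np.zeros((len(self.x_mean), 0))

    @property
    def n_factors(self) -> int:
        return self.W.shape[1]

    def coefficients(self, a: int | None = None) -> tuple[np.ndarray, float]:
        """(coefficient vector, intercept) using the first ``a`` factors."""
        if a is None:
            a = self.n_factors
        if not 0 <= a <= self.n_factors:
            raise ValueError(f"factor count {a} outside fitted range "
                             f"0..{self.n_factors}")
        if a not in self._coef_cache:
            if a == 0:
                beta = np.zeros(len(self.x_mean))
            else:
                beta = self._rotation[:, :a] @ self.q[:a]
            intercept = self.y_mean - float(self.x_mean @ beta)
            self._coef_cache[a] = (beta, intercept)
        return self._coef_cache[a]


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, FeatureMatrix):
        return X.X, list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, None


def pls_fit(X, y, A: int = MAX_FACTORS) -> PLSFit:
    """Fit PLS1 with up to ``A`` factors.

    Deflation stops early if the residual X (or its covariance with y)
    vanishes, so the fitted factor count can be below ``A``; requesting
    more factors than min(n-1, p) raises.
    """
    Xm, columns = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if n < 2 or len(y) != n:
        raise ValueError("need >= 2 aligned samples")
    if A < 1:
        raise ValueError("A must be >= 1")
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")
    x_mean = Xm.mean(axis=0)
    Xc = Xm - x_mean
    ss_x_total = float(np.sum(Xc**2))
    if ss_x_total <= 0:
        raise ValueError("all-constant X")
    y_mean = float(y.mean())
    yc = y - y_mean

    W, P, q, t_ss, xve, yse = [], [], [], [], [], []
    eps = 1e-12 * max(1.0, ss_x_total)
    for _ in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(yc) + 1.0):
            break
        w = w / nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        p_load = Xc.T @ t / tt
        q_f = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_load)
        W.append(w)
        P.append(p_load)
        q.append(q_f)
        t_ss.append(tt)
        xve.append(tt * float(p_load @ p_load) / ss_x_total)
        yse.append(q_f**2 * tt)

    if not W:  # constant y: zero factors, intercept-only model
        W = np.zeros((p, 0))
        P = np.zeros((p, 0))
        return PLSFit(x_mean=x_mean, y_mean=y_mean, W=W, P=P,
                      q=np.zeros(0), t_ss=np.zeros(0),
                      x_var_explained=np.zeros(0), y_ss_explained=np.zeros(0),
                      columns=columns)
    return PLSFit(x_mean=x_mean, y_mean=y_mean,
                  W=np.column_stack(W), P=np.column_stack(P),
                  q=np.array(q), t_ss=np.array(t_ss),
                  x_var_explained=np.array(xve),
                  y_ss_explained=np.array(yse), columns=columns)


def pls_predict(fit: PLSFit, X_new, a: int | None = None) -> np.ndarray:
    """Predict with the first ``a`` factors (all fitted factors by default)."""
    Xm, _ = _as_matrix(X_new)
    if Xm.shape[1] != len(fit.x_mean):
        raise ValueError("column dimension mismatch")
    beta, intercept = fit.coefficients(a)
    return intercept + Xm @ beta


def vip_scores(fit: PLSFit, a: int | None = None) -> np.ndarray:
    """Per-predictor VIP at ``a`` factors."""
    if a is None:
        a = fit.n_factors
    if a < 1 or a > fit.n_factors:
        raise ValueError("a must be in 1..fitted factors")
    ssy = fit.y_ss_explained[:a]
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained y-variance")
    p = fit.W.shape[0]
    # weights are unit norm, so (w_jf/||w_f||)^2 == w_jf^2
    return np.sqrt(p * (fit.W[:, :a] ** 2 @ ssy) / total)


def vip_select(fit: PLSFit, a: int | None = None,
               threshold: float = 1.0) -> list[str]:
    """Predictor names with VIP strictly above the threshold, input order."""
    vip = vip_scores(fit, a)
    names = fit.columns if fit.columns is not None else [
        f"x{j}" for j in range(len(vip))
    ]
    return [nm for nm, v in zip(names, vip) if v > threshold]


def factors_for_variance(fit: PLSFit, fraction: float = 0.99) -> int:
    """Smallest factor count whose cumulative explained X-variance reaches
    ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cum = np.cumsum(fit.x_var_explained)
    idx = np.searchsorted(cum, fraction - 1e-12)
    if idx >= len(cum):
        raise ValueError(f"{fraction:.0%} X-variance not reachable with "
                         f"{fit.n_factors} fitted factors "
                         f"(max {cum[-1] if len(cum) else 0:.4f})")
    return int(idx + 1)


def project_to_factors(fit: PLSFit, X_new, F: int | None = None) -> np.ndarray:
    """Scores of (new) observations on the first ``F`` PLS factors:
    centered data mapped through the rotation W (P'W)^-1."""
    if F is None:
        F = fit.n_factors
    if F > fit.n_factors:
        raise ValueError("F exceeds fitted factors")
    Xm, _ = _as_matrix(X_new)
    if Xm.shape[1] != len(fit.x_mean):
        raise ValueError("column dimension mismatch")
    return (Xm - fit.x_mean) @ fit._rotation[:, :F]
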