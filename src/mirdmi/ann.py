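"""Single-hidden-layer feed-forward regression network with weight decay.

The network maps standardized inputs through ``H`` logistic hidden units to
a linear output and is trained full-batch by minimizing

    sum_i (y_i - yhat_i)^2 + decay * sum(connection weights^2),

with the decay penalty covering the connection weights but not the biases,
so that in the strong-decay limit the network degenerates to the target
mean rather than to zero.  The
objective is minimized with L-BFGS from several seeded random starts, the
best final objective winning, so a fit is deterministic given
``(seed, restarts)``.  Inputs are standardized internally to zero mean and
unit SD — the conventional decay range 1e-4..1e-2 is only meaningful on a
standardized scale — while the target stays in kg with a linear output
unit.

Hyperparameters (hidden nodes, capped at 5 by default, and decay on a
logarithmic grid spanning 1e-4..1e-2) are chosen by grouped cross-
validation with the one-standard-error rule, parsimony ordered: fewer
nodes first, then stronger decay.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize
from scipy.special import expit

from .features import FeatureMatrix

MAX_NODES = 5
DECAY_GRID = tuple(np.logspace(-4, -2, 7))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


@dataclasses.dataclass
class ANNFit:
    """Trained network: input scaling plus the two weight layers."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    W1: np.ndarray        # (p+1) x H, last row = hidden biases
    w2: np.ndarray        # H+1, last entry = output bias
    decay: float
    hidden: int
    objective: float


def _unpack(theta: np.ndarray, p: int, H: int):
    W1 = theta[: (p + 1) * H].reshape(p + 1, H)
    w2 = theta[(p + 1) * H:]
    return W1, w2


def _penalty_mask(p: int, H: int) -> np.ndarray:
    """Boolean mask of penalized parameters (connection weights, not biases)."""
    m1 = np.ones((p + 1, H), dtype=bool)
    m1[p] = False
    m2 = np.ones(H + 1, dtype=bool)
    m2[H] = False
    return np.concatenate([m1.ravel(), m2])


def objective_and_gradient(theta: np.ndarray, Xs: np.ndarray, y: np.ndarray,
                           decay: float, hidden: int):
    """Penalized sum-of-squares objective and its analytic gradient.

    ``Xs`` must already be standardized.  Exposed so the gradient can be
    validated against finite differences.
    """
    n, p = Xs.shape
    W1, w2 = _unpack(theta, p, hidden)
    Z = Xs @ W1[:p] + W1[p]          # n x H pre-activations
    Hid = expit(Z)
    yhat = Hid @ w2[:hidden] + w2[hidden]
    r = yhat - y
    mask = _penalty_mask(p, hidden)
    f = float(r @ r + decay * (theta[mask] @ theta[mask]))
    # backprop
    g2 = np.empty(hidden + 1)
    g2[:hidden] = 2.0 * (Hid.T @ r)
    g2[hidden] = 2.0 * r.sum()
    dHid = np.outer(r, w2[:hidden]) * Hid * (1.0 - Hid)   # n x H
    g1 = np.empty((p + 1, hidden))
    g1[:p] = 2.0 * (Xs.T @ dHid)
    g1[p] = 2.0 * dHid.sum(axis=0)
    grad = np.concatenate([g1.ravel(), g2]) + 2.0 * decay * np.where(mask, theta, 0.0)
    return f, grad


def ann_fit(X, y, hidden: int, decay: float, seed: int = 0,
            restarts: int = 5, maxiter: int = 500) -> ANNFit:
    """Train the network; the best of ``restarts`` seeded starts is kept."""
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if hidden < 1:
        raise ValueError("need at least one hidden node")
    if decay < 0:
        raise ValueError("decay must be >= 0")
    if n <= hidden:
        raise ValueError("need more samples than hidden nodes")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    x_mean = Xm.mean(axis=0)
    x_sd = Xm.std(axis=0)
    x_sd[x_sd == 0] = 1.0    # constant columns pass through as zeros
    Xs = (Xm - x_mean) / x_sd

    rng = np.random.default_rng(seed)
    n_par = (p + 1) * hidden + hidden + 1
    best = None
    for _ in range(max(1, restarts)):
        theta0 = rng.normal(scale=0.7 / np.sqrt(p + 1), size=n_par)
        theta0[-1] = y.mean()   # start the output bias at the target mean
        res = scipy.optimize.minimize(
            objective_and_gradient, theta0, args=(Xs, y, decay, hidden),
            jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    W1, w2 = _unpack(best.x, p, hidden)
    return ANNFit(x_mean=x_mean, x_sd=x_sd, W1=W1.copy(), w2=w2.copy(),
                  decay=decay, hidden=hidden, objective=float(best.fun))


def ann_predict(fit: ANNFit, X_new) -> np.ndarray:
    """Forward pass on new records using the stored input scaling."""
    Xm = _as_matrix(X_new)
    p = len(fit.x_mean)
    if Xm.shape[1] != p:
        raise ValueError("column dimension mismatch")
    Xs = (Xm - fit.x_mean) / fit.x_sd
    Hid = expit(Xs @ fit.W1[:p] + fit.W1[p])
    return Hid @ fit.w2[:fit.hidden] + fit.w2[fit.hidden]


def ann_grid_search(X, y, folds, node_grid=None, decay_grid=None,
                    selection: str = "oneSE", seed: int = 0,
                    restarts: int = 2, maxiter: int = 300):
    """Grouped-CV grid search over (hidden nodes, decay).

    ``folds`` assigns each record to a validation fold (integer labels);
    the assignment must already be cow-independent.  Every grid point is
    scored by the across-fold mean RMSE; under ``selection="oneSE"`` the
    most parsimonious point (fewest nodes, then largest decay) within one
    standard error (SD across folds / sqrt(K)) of the best is returned,
    under ``selection="best"`` the plain minimizer.

    Returns ``(best_hidden, best_decay, table)`` with one table row per
    grid point.
    """
    import pandas as pd

    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    folds = np.asarray(folds)
    node_grid = list(node_grid) if node_grid is not None else list(range(1, MAX_NODES + 1))
    decay_grid = list(decay_grid) if decay_grid is not None else list(DECAY_GRID)
    if not node_grid or not decay_grid:
        raise ValueError("empty hyperparameter grid")
    labels = np.unique(folds)
    if len(labels) < 2:
        raise ValueError("need at least 2 folds")

    # parsimony order: fewer nodes first, then larger decay
    grid = [(h, d) for h in sorted(node_grid) for d in sorted(decay_grid, reverse=True)]
    rows = []
    for h, d in grid:
        fold_rmse = []
        for fl in labels:
            val = folds == fl
            fit = ann_fit(Xm[~val], y[~val], hidden=h, decay=d, seed=seed,
                          restarts=restarts, maxiter=maxiter)
            pred = ann_predict(fit, Xm[val])
            fold_rmse.append(float(np.sqrt(np.mean((pred - y[val]) ** 2))))
        fold_rmse = np.array(fold_rmse)
        rows.append({
            "hidden": h, "decay": d,
            "rmse_cv": float(fold_rmse.mean()),
            "rmse_sd": float(fold_rmse.std(ddof=1)),
            "rmse_se": float(fold_rmse.std(ddof=1) / np.sqrt(len(fold_rmse))),
        })
    table = pd.DataFrame(rows)
    means = table["rmse_cv"].to_numpy()
    best_idx = int(np.argmin(means))
    if selection == "best" or len(grid) == 1:
        chosen = best_idx
    elif selection == "oneSE":
        thr = means[best_idx] + table["rmse_se"].iloc[best_idx]
        chosen = int(np.nonzero(means <= thr)[0][0])
    else:
        raise ValueError(f"unknown selection rule {selection!r}")
    return grid[chosen][0], grid[chosen][1], table
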