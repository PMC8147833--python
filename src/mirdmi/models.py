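"""Fit/predict model wrappers tying constructs to the PLS and ANN engines.

These adapters own the construct encoding (fit on calibration records,
applied functionally to new records) and the model-size searches:

* :class:`PLSModel` picks its factor count by an inner cow-independent CV
  over 1..A factors with the one-standard-error rule.
* :class:`ANNModel` follows the two-stage design for spectra: the MIR block
  is replaced by its projection onto the PLS factors of a DMI~MIR model
  (enough factors to explain 99% of the spectral variance), then a
  single-hidden-layer network is trained, optionally grid-searched over
  (nodes, decay).
* :class:`NRCModel` evaluates the fixed NRC-2001 equation (no fitting).

Calling ``fit`` again simply refits: the wrappers are reusable across CV
splits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ann as ann_engine
from . import pls as pls_engine
from .evaluation import make_cow_folds, one_se_select, rmse
from .features import ConstructEncoder
from .nrc import nrc_predict


def _clamp_factors(A: int, n: int, p: int) -> int:
    return max(1, min(A, n - 1, p))


class PLSModel:
    """PLS regression of DMI on one construct with inner factor selection.

    The factor count is chosen on the calibration records by
    ``inner_folds``-fold cow-independent CV: the least number of factors
    whose CV RMSE is within one SE (SD across folds / sqrt(K)) of the best
    (``selection="oneSE"``), or the plain minimizer (``"best"``), or a
    fixed count (``n_factors``).
    """

    def __init__(self, construct="M19", max_factors: int = pls_engine.MAX_FACTORS,
                 selection: str = "oneSE", n_factors: int | None = None,
                 inner_folds: int = 5, seed: int = 0, fa_panel=None):
        self.construct = construct
        self.max_factors = max_factors
        self.selection = selection
        self.n_factors = n_factors
        self.inner_folds = inner_folds
        self.seed = seed
        self.fa_panel = fa_panel

    def fit(self, records: pd.DataFrame) -> "PLSModel":
        self.encoder_ = ConstructEncoder(self.construct,
                                         fa_panel=self.fa_panel).fit(records)
        fm = self.encoder_.transform(records)
        self._group_tags = list(fm.groups)
        y = records["dmi"].to_numpy(float)
        A = _clamp_factors(self.max_factors, len(y), fm.X.shape[1])
        if self.n_factors is not None:
            self.a_ = min(self.n_factors, A)
        else:
            self.a_ = self._select_factors(records, y, A)
        self.fit_ = pls_engine.pls_fit(fm, y, A=A)
        self.a_ = min(self.a_, max(self.fit_.n_factors, 1))
        return self

    def _select_factors(self, records: pd.DataFrame, y: np.ndarray, A: int) -> int:
        K = min(self.inner_folds, records["cow_id"].nunique())
        if K < 2:
            return A
        plan = make_cow_folds(records, K=K, R=1, seed=self.seed)
        per_fold = []  # K x A rmse table
        for f in range(K):
            cal, val = plan.split(0, f)
            enc = ConstructEncoder(self.construct,
                                   fa_panel=self.fa_panel).fit(records.loc[cal])
            Xc = enc.transform(records.loc[cal])
            Xv = enc.transform(records.loc[val])
            a_max = _clamp_factors(A, int(cal.sum()), Xc.X.shape[1])
            fit = pls_engine.pls_fit(Xc, y[cal], A=a_max)
            row = []
            for a in range(1, A + 1):
                pred = pls_engine.pls_predict(fit, Xv, a=min(a, fit.n_factors))
                row.append(rmse(y[val], pred))
            per_fold.append(row)
        per_fold = np.asarray(per_fold)
        means = per_fold.mean(axis=0)
        ses = per_fold.std(axis=0, ddof=1) / np.sqrt(K)
        if self.selection == "best":
            return int(np.argmin(means)) + 1
        idx = one_se_select(range(1, A + 1), means, ses)
        return idx + 1

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        fm = self.encoder_.transform(records)
        return pls_engine.pls_predict(self.fit_, fm, a=self.a_)

    def vip(self) -> pd.DataFrame:
        """VIP scores of the fitted model at the selected factor count."""
        scores = pls_engine.vip_scores(self.fit_, a=self.a_)
        return pd.DataFrame({"predictor": self.fit_.columns,
                             "group": self._group_tags,
                             "vip": scores})


class ANNModel:
    """Single-hidden-layer network on a construct, MIR block replaced by
    DMI~MIR PLS factor scores (99% spectral variance)."""

    def __init__(self, construct="M19", hidden=None, decay=None,
                 mir_variance: float = 0.99, mir_max_factors: int = pls_engine.MAX_FACTORS,
                 selection: str = "oneSE", inner_folds: int = 5,
                 restarts: int = 2, maxiter: int = 300, seed: int = 0,
                 fa_panel=None):
        self.construct = construct
        self.hidden = hidden          # int -> fixed; None/list -> grid
        self.decay = decay            # float -> fixed; None/list -> grid
        self.mir_variance = mir_variance
        self.mir_max_factors = mir_max_factors
        self.selection = selection
        self.inner_folds = inner_folds
        self.restarts = restarts
        self.maxiter = maxiter
        self.seed = seed
        self.fa_panel = fa_panel

    # -- design matrix with the MIR block projected to PLS factors
    def _design(self, records: pd.DataFrame, fitting: bool) -> np.ndarray:
        fm = self.encoder_.transform(records)
        mir_idx = fm.group_indices("MIR")
        if len(mir_idx) == 0:
            return fm.X
        rest_idx = np.array([i for i in range(fm.X.shape[1])
                             if i not in set(mir_idx)], dtype=int)
        spectra = fm.X[:, mir_idx]
        if fitting:
            y = records["dmi"].to_numpy(float)
            A = _clamp_factors(self.mir_max_factors, len(y), spectra.shape[1])
            self.mir_fit_ = pls_engine.pls_fit(spectra, y, A=A)
            try:
                self.mir_factors_ = pls_engine.factors_for_variance(
                    self.mir_fit_, self.mir_variance)
            except ValueError:
                self.mir_factors_ = self.mir_fit_.n_factors
        scores = pls_engine.project_to_factors(self.mir_fit_, spectra,
                                               F=self.mir_factors_)
        parts = [scores]
        if len(rest_idx):
            parts.append(fm.X[:, rest_idx])
        return np.hstack(parts)

    def build_design(self, records: pd.DataFrame) -> np.ndarray:
        """Fit the encoder and the DMI~MIR factor projection on ``records``
        and return the network's design matrix (MIR block replaced by its
        factor scores).  Useful for external hyperparameter searches."""
        self.encoder_ = ConstructEncoder(self.construct,
                                         fa_panel=self.fa_panel).fit(records)
        return self._design(records, fitting=True)

    def fit(self, records: pd.DataFrame) -> "ANNModel":
        self.encoder_ = ConstructEncoder(self.construct,
                                         fa_panel=self.fa_panel).fit(records)
        X = self._design(records, fitting=True)
        y = records["dmi"].to_numpy(float)
        hidden, decay = self.hidden, self.decay
        fixed = isinstance(hidden, (int, np.integer)) and isinstance(
            decay, (int, float, np.floating)) and not isinstance(decay, bool)
        if fixed:
            self.hidden_, self.decay_ = int(hidden), float(decay)
            self.grid_table_ = None
        else:
            node_grid = ([hidden] if isinstance(hidden, (int, np.integer))
                         else hidden)
            decay_grid = ([decay] if isinstance(decay, (int, float, np.floating))
                          else decay)
            K = min(self.inner_folds, records["cow_id"].nunique())
            plan = make_cow_folds(records, K=K, R=1, seed=self.seed)
            self.hidden_, self.decay_, self.grid_table_ = ann_engine.ann_grid_search(
                X, y, plan.assignments[0], node_grid=node_grid,
                decay_grid=decay_grid, selection=self.selection,
                seed=self.seed, restarts=self.restarts, maxiter=self.maxiter)
        self.fit_ = ann_engine.ann_fit(X, y, hidden=self.hidden_,
                                       decay=self.decay_, seed=self.seed,
                                       restarts=max(self.restarts, 1),
                                       maxiter=max(self.maxiter, 400))
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        X = self._design(records, fitting=False)
        return ann_engine.ann_predict(self.fit_, X)


class NRCModel:
    """NRC-2001 equation as a drop-in model (fit is a no-op)."""

    def __init__(self, fat: str = "pfat", bw: str = "pbw"):
        self.fat = fat
        self.bw = bw

    def fit(self, records: pd.DataFrame) -> "NRCModel":
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return nrc_predict(records, fat=self.fat, bw=self.bw)
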