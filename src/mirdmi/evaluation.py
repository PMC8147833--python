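"""Grouped validation: cow-independent CV, country-independent validation,
metrics, one-standard-error selection and trend summaries.

All cross-validation here is *cow-independent*: every record of a cow falls
on one side of every split, so a model never sees the validation cows
during calibration.  Fold assignment balances record counts and stratifies
by country so each fold mirrors the country mix.  Country-independent
validation trains once on the calibration countries and scores each
held-out country, probing robustness to instrument and management shifts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- metrics

def rmse(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if len(obs) != len(pred) or len(obs) < 1:
        raise ValueError("need equal-length non-empty series")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(obs, pred) -> float:
    """Squared Pearson correlation between observations and predictions."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if len(obs) != len(pred) or len(obs) < 2:
        raise ValueError("need equal-length series with >= 2 points")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("r_squared undefined for a constant series")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def rpd(obs, pred) -> float:
    """Ratio of performance to deviation: sample SD(obs) / RMSE."""
    e = rmse(obs, pred)
    if e == 0:
        raise ValueError("rpd undefined for zero RMSE")
    obs = np.asarray(obs, dtype=float).ravel()
    return float(np.std(obs, ddof=1) / e)


# ------------------------------------------------------------- fold plans

@dataclasses.dataclass
class FoldPlan:
    """R repeats of a K-fold, cow-grouped, country-stratified partition.

    ``assignments`` is an R x n integer array giving each record's
    validation fold per repeat.
    """

    K: int
    R: int
    assignments: np.ndarray
    cow_ids: np.ndarray
    seed: int

    def split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (calibration, validation) record masks."""
        val = self.assignments[repeat] == fold
        return ~val, val

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"cow_id": self.cow_ids})
        for r in range(self.R):
            out[f"repeat_{r}"] = self.assignments[r]
        return out


def make_cow_folds(records: pd.DataFrame, K: int = 10, R: int = 10,
                   seed: int = 0) -> FoldPlan:
    """Assign cows to K folds, R times, balancing record counts within each
    country (greedy: heaviest cow to the lightest fold)."""
    cows = records.groupby(["country", "cow_id"], sort=True).size()
    if cows.index.get_level_values("cow_id").nunique() < K:
        raise ValueError(f"need at least K={K} cows")
    rng = np.random.default_rng(seed)
    cow_fold = {}
    assignments = np.empty((R, len(records)), dtype=int)
    cow_ids = records["cow_id"].to_numpy()
    for r in range(R):
        loads = np.zeros(K, dtype=int)
        cow_fold.clear()
        for country, sub in cows.groupby(level="country"):
            ids = sub.index.get_level_values("cow_id").to_numpy()
            counts = sub.to_numpy()
            order = rng.permutation(len(ids))
            ids, counts = ids[order], counts[order]
            # heaviest first, random tie-break from the permutation above
            for i in np.argsort(-counts, kind="stable"):
                f = int(np.argmin(loads))
                cow_fold[ids[i]] = f
                loads[f] += counts[i]
        assignments[r] = [cow_fold[c] for c in cow_ids]
    return FoldPlan(K=K, R=R, assignments=assignments, cow_ids=cow_ids,
                    seed=seed)


# ------------------------------------------------------- model evaluation

@dataclasses.dataclass
class CVResult:
    """Repeat-level cross-validation summary for one model."""

    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    rpd_mean: float
    per_repeat: pd.DataFrame


def cross_validate(model, records: pd.DataFrame, fold_plan: FoldPlan,
                   pooling: str = "pooled") -> CVResult:
    """Cow-independent cross-validation of a fit/predict model.

    Per repeat, the model is refit on each calibration side and scored on
    the held-out fold; with ``pooling="pooled"`` (default) the repeat's
    out-of-fold predictions are pooled before computing RMSE/R2/RPD, with
    ``pooling="per_fold"`` per-fold RMSEs are averaged.  The summary is the
    mean +/- SD over repeats.
    """
    if pooling not in ("pooled", "per_fold"):
        raise ValueError("pooling must be 'pooled' or 'per_fold'")
    y = records["dmi"].to_numpy(dtype=float)
    rows = []
    for r in range(fold_plan.R):
        pred = np.full(len(records), np.nan)
        fold_rmses = []
        for f in range(fold_plan.K):
            cal, val = fold_plan.split(r, f)
            if not val.any():
                continue
            if not cal.any():
                raise ValueError("degenerate fold: empty calibration side")
            model.fit(records.loc[cal])
            pred[val] = model.predict(records.loc[val])
            fold_rmses.append(rmse(y[val], pred[val]))
        if np.isnan(pred).any():
            raise ValueError("degenerate fold plan: unpredicted records")
        if pooling == "pooled":
            rep_rmse = rmse(y, pred)
        else:
            rep_rmse = float(np.mean(fold_rmses))
        rows.append({
            "repeat": r,
            "rmse": rep_rmse,
            "r2": r_squared(y, pred),
            "rpd": rpd(y, pred),
        })
    per_repeat = pd.DataFrame(rows)
    return CVResult(
        rmse_mean=float(per_repeat["rmse"].mean()),
        rmse_sd=float(per_repeat["rmse"].std(ddof=1)) if len(rows) > 1 else 0.0,
        r2_mean=float(per_repeat["r2"].mean()),
        rpd_mean=float(per_repeat["rpd"].mean()),
        per_repeat=per_repeat,
    )


def one_se_select(complexities, cv_mean, cv_se) -> int:
    """Index of the least complex candidate within one SE of the best.

    Candidates must be ordered by increasing complexity; the threshold is
    min(cv_mean) plus the SE at the argmin.
    """
    complexities = list(complexities)
    means = np.asarray(cv_mean, dtype=float)
    ses = np.asarray(cv_se, dtype=float)
    if len(complexities) == 0:
        raise ValueError("no candidates")
    if not (len(complexities) == len(means) == len(ses)):
        raise ValueError("misaligned candidate arrays")
    if any(c2 < c1 for c1, c2 in zip(complexities, complexities[1:])):
        raise ValueError("candidates must be ordered by complexity")
    best = int(np.argmin(means))
    thr = means[best] + ses[best]
    return int(np.nonzero(means <= thr)[0][0])


def country_independent_validate(model, calibration: pd.DataFrame,
                                 validation: pd.DataFrame) -> dict[str, float]:
    """Fit once on the calibration countries, report RMSE per held-out
    country.  Calibration and validation country sets must be disjoint."""
    cal_countries = set(calibration["country"])
    val_countries = set(validation["country"])
    overlap = cal_countries & val_countries
    if overlap:
        raise ValueError(f"countries in both sets: {sorted(overlap)}")
    model.fit(calibration)
    out = {}
    for country, sub in validation.groupby("country"):
        out[str(country)] = rmse(sub["dmi"], model.predict(sub))
    return out


def construct_sweep(records: pd.DataFrame, constructs, model_factory,
                    fold_plan: FoldPlan,
                    validation_by_country: pd.DataFrame | None = None) -> pd.DataFrame:
    """Evaluate a list of constructs with one row per construct:
    RMSE_cv mean +/- SD, R2_cv, RPD_cv and, if an external validation table
    is given, RMSE_v per held-out country."""
    rows = []
    for construct in constructs:
        model = model_factory(construct)
        cv = cross_validate(model, records, fold_plan)
        row = {
            "construct": construct,
            "rmse_cv": cv.rmse_mean,
            "rmse_cv_sd": cv.rmse_sd,
            "r2_cv": cv.r2_mean,
            "rpd_cv": cv.rpd_mean,
        }
        if validation_by_country is not None and len(validation_by_country):
            rmse_v = country_independent_validate(
                model_factory(construct), records, validation_by_country)
            for country, value in sorted(rmse_v.items()):
                row[f"rmse_v_{country}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_trends(predictions: pd.DataFrame,
                     value: str = "pred") -> dict[str, pd.DataFrame]:
    """Plain arithmetic means of a prediction column by week of lactation
    and, when a ``month`` column exists, by calendar month (no smoothing)."""
    if len(predictions) == 0:
        raise ValueError("no predictions to summarize")
    out = {}
    weekly = predictions.groupby("wol", sort=True)[value].agg(["mean", "size"])
    out["weekly"] = weekly.reset_index().rename(columns={"mean": value, "size": "n"})
    if "month" in predictions.columns:
        monthly = predictions.groupby("month", sort=True)[value].agg(["mean", "size"])
        out["monthly"] = monthly.reset_index().rename(columns={"mean": value, "size": "n"})
    return out
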