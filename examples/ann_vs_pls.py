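"""Neural network vs PLS when the intake response saturates.

With a logistic (saturating) dependence of DMI on milk yield, a linear
model leaves structured error that a single-hidden-layer network with
weight decay can capture.  The ANN sees the same M19 predictors, with the
spectra replaced by their DMI~MIR PLS factor scores (99% of spectral
variance) to keep the network small.
"""

import numpy as np

from mirdmi import ANNModel, GeneratorConfig, PLSModel, PipelineConfig, rmse
from mirdmi.pipeline import clean_records
from mirdmi.synthetic import generate_population

cfg = GeneratorConfig(seed=100, n_cows_per_country=25, residual_sd=1.5,
                      saturating_my=True)
records, _ = generate_population(cfg)
clean, _, _ = clean_records(records, PipelineConfig())

# hold out a quarter of the cows in each country
rng = np.random.default_rng(0)
hold = set()
for _, sub in clean[["country", "cow_id"]].drop_duplicates().groupby("country"):
    ids = sub["cow_id"].to_numpy()
    rng.shuffle(ids)
    hold.update(ids[: len(ids) // 4])
val = clean["cow_id"].isin(hold)
cal, held = clean[~val], clean[val]

pls = PLSModel("M19", seed=1).fit(cal)
ann = ANNModel("M19", hidden=2, decay=1e-4, seed=1, restarts=3, maxiter=1500).fit(cal)
rp = rmse(held["dmi"], pls.predict(held))
ra = rmse(held["dmi"], ann.predict(held))
print(f"held-out cows: {held.cow_id.nunique()} ({len(held)} records)")
print(f"PLS M19 RMSE: {rp:.3f} kg")
print(f"ANN M19 RMSE: {ra:.3f} kg  (hidden nodes = 2, decay = 1e-4)")
print(f"-> the network recovers the saturating milk-yield effect the linear")
print(f"   model cannot, cutting held-out error by {100*(rp-ra)/rp:.0f}%.")
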