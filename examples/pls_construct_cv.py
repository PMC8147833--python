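"""Cow-independent cross-validation of PLS constructs.

Constructs M1-M22 combine seven predictor groups (MIR spectrum, parity,
week of lactation, milk yield, predicted bodyweight, fatty acids, milk
composition).  Cross-validation is cow-grouped: all records of a cow stay
on one side of every split, so the score reflects prediction for unseen
animals.
"""

from mirdmi import (
    GeneratorConfig,
    PLSModel,
    PipelineConfig,
    clean_records,
    construct_sweep,
    generate_population,
    make_cow_folds,
)

records, _ = generate_population(GeneratorConfig(seed=2, n_cows_per_country=30))
clean, _, counts = clean_records(records, PipelineConfig())
print(f"cleaned: {counts['after_gh_filter']}/{counts['input']} records, "
      f"{counts['windowed_points']} spectral points retained")

plan = make_cow_folds(clean, K=5, R=2, seed=3)
report = construct_sweep(clean, ["M1", "M5", "M15", "M19"],
                         lambda c: PLSModel(c, seed=0), plan)
print(report.round(3).to_string(index=False))
print("-> adding covariates to the spectrum (M15/M19) lowers RMSE_cv toward the")
print("   3 kg residual noise floor; single-group models (M1 spectra only, M5")
print("   milk yield only) explain less of the intake variance.")
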