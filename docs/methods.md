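# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `mirdmi`.

## The prediction problem

One observation is a milk test-day of one cow: identifiers (cow,
country), covariates (parity, week of lactation WOL, milk yield MY), the
measured dry matter intake DMI (kg/d, the target), a MIR absorbance
spectrum (log 1/T) on a wavenumber grid, and MIR-*predicted* quantities
that in practice come from prior calibration equations — bodyweight
(pBW), milk fat/protein/lactose (pMC) and a fatty-acid panel (pFA).
Models are judged by how well they predict DMI for **unseen cows**
(cow-independent cross-validation) and for **unseen countries**
(country-independent validation), the latter probing robustness to
instrument and management differences.

## Preprocessing

Spectra from different instruments are linearly interpolated onto a
common inclusive grid of 797 points spanning 925.66–3995.78 cm⁻¹
(no extrapolation). Only points strictly inside the open windows
(950, 1600) ∪ (1750, 1800) ∪ (2600, 3000) cm⁻¹ are kept — the regions
informative about milk composition, excluding the water-dominated
bands. On the uniform 797-point grid this retains **284** points; the
count depends on the exact grid, so the package records its own number
rather than assuming one.

Record filters: 10 ≤ DMI ≤ 34 kg/d and MY ≥ 10 kg/d, boundaries kept.

**GH spectral outlier filter.** PCA (SVD on centered, unscaled spectra)
retains the smallest number k of components whose cumulative explained
variance reaches 99 %. Each record's squared Mahalanobis distance is the
sum of its squared SD-standardized scores; GH is that distance divided
by k, and records with GH > 5 are removed. Two deliberate choices:

- the distance is **squared** before dividing by k (the convention of
  the chemometric GH literature);
- the filter is **iterative** (remove, refit, repeat until stable,
  ≤ 10 passes). A single pass is provably masked by gross contamination:
  a block of outliers at fraction ε inflates the variance along its own
  direction so that its standardized distance saturates near
  √((1−ε)/ε) ≈ 4.4 SD at ε = 5 %, below the GH > 5 threshold for any
  shift magnitude. Refitting on the cleaned remainder removes the mask,
  and makes the filter idempotent by construction. Measured on planted
  8-SD outliers at 5 %: sensitivity 100 %, specificity ≥ 99.4 % across
  20 seeds; clean cohorts lose ≤ 0.1 %.

## Feature constructs

Seven groups — MIR, PRT, WOL, MY, pBW, pFA, pMC — combine into the 22
constructs M1…M22 (`mirdmi.features.CONSTRUCTS`), from single groups
(M1 = MIR, …, M7 = pMC) to the full M22. Ordinal predictors use
**discrete orthonormal polynomial contrasts**: k ordered categories give
k−1 columns that are exactly orthonormal and orthogonal to the constant
at the fitting scores. Parity uses the fixed three-level space
(first / second / third+); WOL uses the weeks observed in the
calibration set. The contrasts are built by fully re-orthogonalized
Gram–Schmidt on 1, x·p₀, x·p₁, … with the projection coefficients
stored, so the same polynomials can be **evaluated functionally** at
prediction time — an unseen week yields finite polynomial
extrapolation instead of an error. Fatty acids enter as percent of milk
fat (100·fa/fat); the default pFA panel is the six VIP-retained acids
C8:0, C10:0, C12:0, C14:0, C18:0, C18:1 cis-9, overridable by a
VIP-selection run.

*Limitation*: with many observed weeks the trailing contrasts have high
polynomial degree; evaluating them far outside the calibration range
(e.g. week 43 from a 1–23 training range) is numerically explosive.
Experiment designs here therefore validate only on in-range weeks, and
external validations of WOL-bearing constructs on countries with wider
lactation coverage should be read with that in mind.

## PLS engine

PLS1 by NIPALS on column-centered, unscaled data (spectral channels
share units; scaling is deliberately omitted). For univariate y each
factor is exact in one pass: w = X'y/‖X'y‖, t = Xw, p = X't/t't,
q = y't/t't, then X ← X − tp'. Coefficients for any truncation a are
B_a = W_a(P_a'W_a)⁻¹q_a, cached so model-size searches are cheap; the
default ceiling is 20 factors. Per-factor explained X-variance
(t't·‖p‖²/‖X_c‖²) drives `factors_for_variance`, and
`project_to_factors` maps centered spectra through W(P'W)⁻¹ — the
representation the ANN uses. VIP scores follow the standard definition
with SSY_f = q_f²·t_f't_f; ΣVIP² = p holds identically. Deflation stops
early when the residual covariance vanishes (constant y gives the
intercept-only model).

Factor-count selection inside `PLSModel` uses an inner cow-grouped
5-fold CV over a = 1…20 and the **one-SE rule**: the threshold is the
minimum CV RMSE plus its SE (SD across folds/√K) and the smallest a
under the threshold wins. `selection="best"` takes the plain minimizer.

## ANN engine

A single hidden layer of H logistic units (H ≤ 5) with a linear output,
trained full-batch by L-BFGS on
Σ(y−ŷ)² + λ·Σ(connection weights²). Biases are excluded from the
penalty so the strong-decay limit degenerates to the target mean rather
than to zero. Inputs are standardized internally (decay magnitudes
1e-4…1e-2 are only meaningful on a standardized scale); the target stays
in kg. Training uses seeded random restarts (default 5 in the engine,
2 in searches), best final objective kept, so a fit is deterministic
given (seed, restarts). The analytic gradient is validated against
central finite differences to < 1e-5 relative error.

Hyperparameters are grid-searched by grouped CV — nodes 1…5 by default,
decay on a 7-point logarithmic grid spanning 1e-4…1e-2 — with the
one-SE rule under a parsimony order of fewer nodes first, then larger
decay. The SE is taken across folds; an alternative would be the SD
across repeats, which is exposed through the CV tables.

For constructs containing MIR, the spectra are replaced by their scores
on the first F factors of a DMI~MIR PLS fit, F chosen to explain 99 % of
the spectral variance (typically 4–6 on the synthetic cohorts). This
keeps the network small without discarding composition information.

## Validation machinery

`make_cow_folds` builds R repeats of K folds (default 10×10) that are
cow-grouped and country-stratified: within each country, cows are
shuffled and assigned heaviest-first to the currently lightest fold, so
folds hold ≈ 10 % of records each and mirror the country mix.
Stratification is not strictly required by cow-independence; it reduces
the variance of fold scores. `cross_validate` refits the model per
split, pools each repeat's out-of-fold predictions (per-fold averaging
is available as an option) and reports mean ± SD over repeats of
RMSE, R² (squared Pearson correlation) and RPD (SD(obs)/RMSE). R² for a
constant series raises rather than silently returning 0.
`country_independent_validate` refuses overlapping country sets and
scores one fit per held-out country.

## NRC-2001 baseline

FCM = 0.4·MY + 15·(MY·fat%/100);
DMI = (0.372·FCM + 0.0968·BW^0.75)·(1 − exp(−0.192·(WOL + 3.67))).
The coefficients sit in one constants block (`mirdmi.nrc`) for auditing.
By default the MIR-predicted fat (`pfat`) feeds FCM and `pbw` supplies
bodyweight — the quantities actually available at scale — with column
names switchable.

## Synthetic study conditions

The generator defines the conditions every test runs under. Per cow:
country, parity (35/30/35 % for 1/2/3+), a bodyweight around
545 kg (+25/+45 kg for older parities, SD 40), a milk-yield scale around
23 kg (+1.2 kg for parity ≥ 2, SD 2.2) and a calving month. Per week of
lactation within the country's range (AUS 6–23, CAN 1–43, GPE 1–8):

- MY follows a Wood-type curve `w^0.3·e^(−0.04w)` (peak ≈ week 7) with
  1.2 kg record noise;
- a latent energy-balance factor u declines from calving
  (1.2·e^(−w/10) − 0.24 + N(0, 0.8));
- milk fat ≈ 4.2 − 0.05(MY−25) + 0.15u g/dL; protein and lactose vary
  around 3.45 and 4.75 g/dL;
- each fatty acid is its typical fraction of fat modulated by u
  (long chains up, de-novo chains down) and, for the six signal FAs, an
  independent metabolic factor v_g whose relative swing is larger for
  the minor de-novo acids (18–72 %);
- noiseless DMI = 15.3 + lactation shape + 0.25(MY−25) + 0.012(BW−575)
  + parity increment (0/0.8/1.4) − 0.3u + 0.4(fat−4.2) + Σ c_g v_g,
  with the lactation shape `8(1−e^(−0.25(w−0.5))) − 0.10w` placing the
  pooled weekly peak in weeks 10–14 and the trough at week 1; measured
  DMI adds N(0, residual_sd), default 3.0 kg.

Spectra are low-rank: eight unit-norm Gaussian-band pure components
(fat, protein, lactose, short/medium/long-chain FA groups, citrate,
urea) weighted by the record's concentrations, plus a smooth
country-specific offset drawn inside the informative windows
(instrument differences concentrate where absorption happens), an
optional per-country multiplicative band gain (response-scale
differences of unstandardized spectrometers), and i.i.d. noise
(5e-4 absorbance). Fat and protein dominate the spectral variance so
99 %-variance truncations need only a handful of components. The
MIR-predicted covariates are noisy linear readouts of the generating
quantities (pBW ± 12 kg, composition ± 0.05 g/dL, pFA ± 1 %), as they
would be in reality — which is why even at residual_sd = 0 a model
cannot reach zero error (the floor is ≈ 0.7 kg on the default cohort).

The per-FA coefficients and swings were chosen so that the designed
ground truth is actually recoverable by the stated workflows: each of
the six signal FAs clears VIP > 1 on a pooled cohort while nothing else
does, and the full-construct cow-independent RMSE converges to the
planted residual SD. Two generator options define stress scenarios
rather than defaults: `saturating_my` replaces the linear milk-yield
effect with a logistic one (gain 6.5 kg, center 27 kg, width 1.5 kg) to
create a nonlinearity a linear model cannot capture, and the per-country
offset/gain/MY-scale maps emulate a badly standardized instrument for
distribution-shift experiments.

What the generator does **not** emulate: physically meaningful band
assignments, genetic/pedigree structure, diet composition, seasonal
feeding effects on DMI (the calendar month is bookkeeping only), herd
effects, or autocorrelated within-cow residuals. Passing tests
demonstrate that the machinery recovers planted structure under these
conditions, not that any particular accuracy would be achieved on real
multi-country data.

## Designed experiments behind the end-to-end tests

- *Noise-floor recovery*: σ = 3.0 kg, ~2000 records (29 cows/country),
  construct M19, 10-fold × 3-repeat cow-independent CV → RMSE_cv within
  5 % of σ.
- *Nonlinearity advantage*: saturating_my with σ = 1.5 kg, 25
  cows/country, a quarter of cows held out; ANN (2 nodes, decay 1e-4)
  vs PLS M19 with one-SE factors. The lower σ isolates the nonlinear
  signal (~0.6–0.8 kg) from the noise.
- *Country-shift degradation*: all three countries get distinct
  instrument characteristics (offsets 0.08, gains 1.2/1.0/0.8, MY
  scales 0.9/1.0/0.85) at σ = 1.5 kg; for each pairwise-union
  calibration the held-out country's RMSE_v is compared with the
  calibration's own RMSE_cv, averaged over the three holdouts per seed.
  M15 is used (no WOL, avoiding out-of-range polynomial evaluation for
  the CAN holdout; no pFA, so the corrupted spectra cannot be bypassed
  through clean FA readouts).
- *GH recovery*: single-country cohorts (~1030 records), 5 % outliers
  at 8 SD.

Problem sizes throughout (25–100 cows per country, 3–5 CV repeats) are
the package's chosen working scale: large enough that Monte-Carlo
variability does not dominate the designed effects, small enough to
iterate quickly.

## Numerical notes

- Contrast bases: two-pass re-orthogonalization keeps M'M = I to
  ~1e-15 up to k = 50; evaluation replays the identical recurrence, so
  contrasts and functional evaluation agree bitwise at the nodes.
- PLS deflation tolerances: a factor stops the loop when ‖X'y‖ or t't
  falls below ~1e-12 of scale.
- GH: scores are standardized by s_k/√(n−1); the mean spectrum has
  GH = 0 exactly.
- L-BFGS runs with ftol 1e-12 / gtol 1e-8; restarts draw initial
  weights N(0, 0.7/√(p+1)) with the output bias started at mean(y).
- All randomness flows from explicit integer seeds; a pipeline run
  stream-splits one root seed per stage and stamps outputs with the
  seed and a hash of the scientific configuration.
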