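"""Multi-country synthetic cohorts of milk test-day records.

The generator emulates the statistical structure of restricted
calibration datasets for DMI prediction from milk MIR spectra:

* three country blocks with different lactation-stage coverage — GPE
  records concentrate in early lactation (weeks 1-8), AUS in mid lactation
  (weeks 6-23) and CAN spans the whole lactation (weeks 1-43);
* country-specific smooth spectral offsets (instrument/standardization
  differences);
* DMI within a plausible 10-34 kg/d band, with known ground-truth
  dependence on milk yield, bodyweight, parity, week of lactation and the
  spectrum-linked milk composition.

Milk yield follows a Wood-type lactation curve peaking near week 7; the
intake lactation shape is a saturating rise minus a linear decline,
``8*(1 - exp(-0.25*WOL)) - 0.10*WOL``, whose pooled weekly mean peaks in
weeks 10-14.  Spectra are low-rank: eight synthetic pure-component
absorbance bands (fat, protein, lactose, short/medium/long-chain fatty
acid groups, citrate and urea) weighted by per-record concentrations, plus
the country offset and i.i.d. noise; the fat and protein bands dominate
the spectral variance so that "99% variance" PCA/PLS truncations are
meaningful at small component counts.  The MIR-predicted covariates (pBW,
pMC, pFA) are noisy linear readouts of the same generating quantities, as
they would be in practice where they come from prior MIR prediction
equations.

Everything is drawn from one `numpy` Generator seeded by the config, so a
given seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocessing import GRID_MAX, GRID_MIN, N_POINTS, make_common_grid
from .records import fa_slug, spectral_col

#: Fatty-acid panel generated per record (g/dL of milk).
FA_PANEL = (
    "C4:0", "C6:0", "C8:0", "C10:0", "C12:0", "C14:0", "C16:0",
    "C18:0", "C18:1 cis-9", "C18:2 cis-9,12",
)

#: Typical proportion of each FA in milk fat (%), used as generation means.
FA_FRACTION = {
    "C4:0": 3.0, "C6:0": 2.0, "C8:0": 1.3, "C10:0": 3.0, "C12:0": 3.5,
    "C14:0": 11.0, "C16:0": 30.0, "C18:0": 10.0, "C18:1 cis-9": 23.0,
    "C18:2 cis-9,12": 2.0,
}

#: Loading of each FA on the latent energy-balance factor ``u``: body-fat
#: mobilization raises long-chain FAs in milk and dilutes de-novo
#: short/medium chains.  Zero-loading FAs are pure nuisance variation.
FA_U_LOADING = {
    "C4:0": 0.0, "C6:0": 0.0, "C8:0": -1.0, "C10:0": -1.1, "C12:0": -0.9,
    "C14:0": -0.8, "C16:0": 0.0, "C18:0": 1.0, "C18:1 cis-9": 1.2,
    "C18:2 cis-9,12": 0.0,
}

#: FAs that carry DMI signal: besides the shared energy-balance factor,
#: each has an independent metabolic factor entering DMI with this
#: coefficient (kg per SD), so every one of them is individually
#: informative and VIP screening can recover the full set.
FA_DMI_COEF = {
    "C8:0": -0.84, "C10:0": -0.76, "C12:0": -0.68, "C14:0": -0.48,
    "C18:0": 0.46, "C18:1 cis-9": 0.30,
}
SIGNAL_FAS = tuple(FA_DMI_COEF)

#: Relative SD of each signal FA's own metabolic factor in its milk-fat
#: proportion.  De-novo short/medium-chain FAs swing proportionally more
#: than the abundant long chains, which also keeps every signal FA's
#: absolute covariance with DMI well above the finite-sample noise floor.
FA_V_LOADING = {
    "C8:0": 0.72, "C10:0": 0.60, "C12:0": 0.50, "C14:0": 0.34,
    "C18:0": 0.30, "C18:1 cis-9": 0.18,
}

_DEFAULT_WOL_RANGES = {"AUS": (6, 23), "CAN": (1, 43), "GPE": (1, 8)}

#: Ground-truth DMI model coefficients (kg/d units).
TRUE_COEF = {
    "intercept": 15.3,
    "shape_rise": 8.0,       # saturating-rise amplitude, kg
    "shape_rate": 0.25,      # 1/week
    "shape_offset": -0.5,    # weeks; deepens the week-1 trough
    "shape_decline": 0.10,   # kg/week linear decline
    "my_slope": 0.25,        # kg DMI per kg milk (linear regime)
    "sat_gain": 6.5,         # kg, logistic MY dependence (saturating option)
    "sat_center": 27.0,      # kg milk
    "sat_width": 1.5,        # kg milk
    "bw_slope": 0.012,       # kg DMI per kg bodyweight
    "bw_ref": 575.0,
    "parity_add": (0.0, 0.8, 1.4),   # parity 1 / 2 / 3+
    "u_slope": -0.3,         # kg DMI per SD of energy-balance factor
    "fat_slope": 0.4,        # kg DMI per g/dL milk fat
    "fat_ref": 4.2,
}


def lactation_shape(wol, coef: Mapping = TRUE_COEF):
    """Intake lactation shape: a*(1-exp(-c*(WOL+b))) - d*WOL (kg)."""
    wol = np.asarray(wol, dtype=float)
    return (coef["shape_rise"]
            * (1.0 - np.exp(-coef["shape_rate"] * (wol + coef["shape_offset"])))
            - coef["shape_decline"] * wol)


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohorts."""

    country_labels: tuple[str, ...] = ("AUS", "CAN", "GPE")
    n_cows_per_country: int | Mapping[str, int] = 200
    wol_ranges: Mapping[str, tuple[int, int]] | None = None
    residual_sd: float = 3.0                 # kg, i.i.d. DMI noise
    country_spectral_offset_scale: float | Mapping[str, float] = 0.015
    parity_probs: tuple[float, float, float] = (0.35, 0.30, 0.35)
    seed: int = 0
    n_wavenumbers: int = N_POINTS
    grid_min: float = GRID_MIN
    grid_max: float = GRID_MAX
    spectral_noise_sd: float = 5e-4          # absorbance units per point
    country_my_scale: Mapping[str, float] | None = None
    country_spectral_gain: Mapping[str, float] | None = None
    saturating_my: bool = False              # logistic instead of linear MY term
    dmi_band: tuple[float, float] = (15.0, 25.0)  # design band for country means

    def __post_init__(self):
        if abs(sum(self.parity_probs) - 1.0) > 1e-12:
            raise ValueError("parity_probs must sum to 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.wol_ranges is None:
            self.wol_ranges = {
                c: _DEFAULT_WOL_RANGES.get(c, (1, 30)) for c in self.country_labels
            }
        for c in self.country_labels:
            if c not in self.wol_ranges:
                raise ValueError(f"no WOL range for country {c!r}")
            lo, hi = self.wol_ranges[c]
            if not (1 <= lo <= hi):
                raise ValueError(f"empty WOL range for {c!r}")
        if isinstance(self.n_cows_per_country, Mapping):
            unknown = set(self.n_cows_per_country) - set(self.country_labels)
            if unknown:
                raise ValueError(f"unknown country label(s): {sorted(unknown)}")
            counts = [self.n_cows_per_country.get(c, 0) for c in self.country_labels]
        else:
            counts = [self.n_cows_per_country] * len(self.country_labels)
        if any(n <= 0 for n in counts):
            raise ValueError("cow counts must be positive")

    def cows_in(self, country: str) -> int:
        if isinstance(self.n_cows_per_country, Mapping):
            return int(self.n_cows_per_country[country])
        return int(self.n_cows_per_country)

    def offset_scale(self, country: str) -> float:
        s = self.country_spectral_offset_scale
        return float(s[country]) if isinstance(s, Mapping) else float(s)

    def my_scale(self, country: str) -> float:
        if self.country_my_scale is None:
            return 1.0
        return float(self.country_my_scale.get(country, 1.0))

    def spectral_gain(self, country: str) -> float:
        """Multiplicative instrument response on the component bands; a
        gain away from 1 emulates an unstandardized spectrometer whose
        absorbance scale differs from the reference instruments."""
        if self.country_spectral_gain is None:
            return 1.0
        return float(self.country_spectral_gain.get(country, 1.0))


@dataclasses.dataclass
class GroundTruth:
    """Noiseless quantities behind a generated cohort."""

    records: pd.DataFrame             # noiseless DMI, u, concentrations, bw
    coefficients: dict
    country_offsets: dict[str, np.ndarray]
    bands: np.ndarray                 # component x wavenumber, unit norm
    component_names: tuple[str, ...]
    grid: np.ndarray


def _gaussian_bands(grid: np.ndarray, centers, widths) -> np.ndarray:
    band = np.zeros_like(grid)
    for c, w in zip(centers, widths):
        band += np.exp(-0.5 * ((grid - c) / w) ** 2)
    return band / np.linalg.norm(band)


def _component_bands(grid: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    """Synthetic pure-component absorbance bands (unit L2 norm), with all
    centers inside the informative windows."""
    spec = {
        "fat": ([1770.0, 2855.0, 2925.0], [12.0, 18.0, 18.0]),
        "protein": ([1548.0, 1245.0], [20.0, 25.0]),
        "lactose": ([1045.0, 1075.0], [15.0, 12.0]),
        "sc_fa": ([1160.0, 2870.0], [14.0, 12.0]),
        "mc_fa": ([1190.0, 2910.0], [14.0, 12.0]),
        "lc_fa": ([1310.0, 2940.0], [16.0, 12.0]),
        "citrate": ([1390.0], [14.0]),
        "urea": ([1460.0], [16.0]),
    }
    names = tuple(spec)
    bands = np.vstack([_gaussian_bands(grid, c, w) for c, w in spec.values()])
    return bands, names


#: Spectral gain per component: absorbance per (g/dL) of the component
#: concentration.  Fat and protein dominate so the spectral variance is
#: concentrated in few principal components.
COMPONENT_GAIN = {
    "fat": 1.0, "protein": 1.4, "lactose": 0.6, "sc_fa": 0.30,
    "mc_fa": 0.10, "lc_fa": 0.13, "citrate": 0.40, "urea": 1.0,
}


def _smooth_offset(rng: np.random.Generator, grid: np.ndarray,
                   scale: float) -> np.ndarray:
    """Smooth country offset: a few broad Gaussian humps, ~scale absorbance.

    Hump centers are drawn inside the informative windows — instrument
    response differences concentrate in the absorbing regions — so the
    offset survives window selection."""
    from .preprocessing import DEFAULT_WINDOWS
    windows = np.array(DEFAULT_WINDOWS)
    widths = windows[:, 1] - windows[:, 0]
    out = np.zeros_like(grid)
    for _ in range(4):
        w = rng.choice(len(windows), p=widths / widths.sum())
        center = rng.uniform(*windows[w])
        width = rng.uniform(30.0, 120.0)
        out += rng.normal() * np.exp(-0.5 * ((grid - center) / width) ** 2)
    peak = np.max(np.abs(out))
    return scale * out / peak if peak > 0 else out


def generate_population(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one cohort: a record table plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    grid = make_common_grid(config.n_wavenumbers, config.grid_min, config.grid_max)
    bands, comp_names = _component_bands(grid)
    coef = dict(TRUE_COEF)

    offsets = {c: _smooth_offset(rng, grid, config.offset_scale(c))
               for c in config.country_labels}

    rows, truth_rows = [], []
    spectra = []
    for country in config.country_labels:
        lo, hi = config.wol_ranges[country]
        weeks = np.arange(lo, hi + 1)
        for i in range(config.cows_in(country)):
            cow_id = f"{country}_{i + 1:04d}"
            cat = int(rng.choice([1, 2, 3], p=config.parity_probs))
            parity = cat if cat < 3 else 3 + int(rng.poisson(0.7))
            bw = max(350.0, 545.0 + 25.0 * (cat == 2) + 45.0 * (cat == 3)
                     + rng.normal(0.0, 40.0))
            my_level = (23.0 + 1.2 * (cat >= 2) + rng.normal(0.0, 2.2)) \
                * config.my_scale(country)
            calving_month = int(rng.integers(1, 13))
            for wol in weeks:
                wood = wol**0.3 * np.exp(-0.04 * wol)
                my = max(1.0, my_level * wood + rng.normal(0.0, 1.2))
                u = (1.2 * np.exp(-wol / 10.0) - 0.24 + rng.normal(0.0, 0.8))
                fat = max(1.5, coef["fat_ref"] - 0.05 * (my - 25.0)
                          + 0.15 * u + rng.normal(0.0, 0.2))
                protein = max(1.5, 3.45 - 0.02 * (my - 25.0) + rng.normal(0.0, 0.13))
                lactose = max(3.0, 4.75 + rng.normal(0.0, 0.08))
                fa = {}
                fa_factors = {}
                for name in FA_PANEL:
                    v = rng.normal() if name in FA_DMI_COEF else 0.0
                    fa_factors[name] = v
                    rel = (1.0 + 0.08 * FA_U_LOADING[name] * u
                           + FA_V_LOADING.get(name, 0.0) * v
                           + 0.015 * rng.normal())
                    fa[name] = max(0.0, FA_FRACTION[name] / 100.0 * fat * rel)
                sc = fa["C4:0"] + fa["C6:0"] + fa["C8:0"] + fa["C10:0"]
                mc = fa["C12:0"] + fa["C14:0"] + fa["C16:0"]
                lc = fa["C18:0"] + fa["C18:1 cis-9"] + fa["C18:2 cis-9,12"]
                citrate = max(0.0, 0.17 + rng.normal(0.0, 0.02))
                urea = max(0.0, 0.030 + rng.normal(0.0, 0.006))

                if config.saturating_my:
                    my_term = (coef["sat_gain"]
                               * expit((my - coef["sat_center"]) / coef["sat_width"])
                               - 0.35 * coef["sat_gain"])
                else:
                    my_term = coef["my_slope"] * (my - 25.0)
                noiseless = (
                    coef["intercept"]
                    + lactation_shape(wol, coef)
                    + my_term
                    + coef["bw_slope"] * (bw - coef["bw_ref"])
                    + coef["parity_add"][cat - 1]
                    + coef["u_slope"] * u
                    + coef["fat_slope"] * (fat - coef["fat_ref"])
                    + sum(FA_DMI_COEF[n] * fa_factors[n] for n in FA_DMI_COEF)
                )
                dmi = noiseless + rng.normal(0.0, config.residual_sd) \
                    if config.residual_sd > 0 else noiseless

                conc = np.array([fat, protein, lactose, sc, mc, lc, citrate, urea])
                gains = np.array([COMPONENT_GAIN[n] for n in comp_names])
                spectrum = (config.spectral_gain(country)
                            * (conc * gains) @ bands + offsets[country]
                            + rng.normal(0.0, config.spectral_noise_sd, len(grid)))
                spectra.append(spectrum)

                month = (calving_month - 1 + int(round((wol - 1) * 7 / 30.44))) % 12 + 1
                row = {
                    "cow_id": cow_id, "country": country, "parity": parity,
                    "wol": int(wol), "month": month,
                    "my": my, "dmi": dmi,
                    "pbw": bw + rng.normal(0.0, 12.0),
                    "pfat": max(0.5, fat + rng.normal(0.0, 0.05)),
                    "pprot": max(0.5, protein + rng.normal(0.0, 0.05)),
                    "plact": max(0.5, lactose + rng.normal(0.0, 0.05)),
                }
                for name in FA_PANEL:
                    row[fa_slug(name)] = max(0.0, fa[name] * (1.0 + 0.01 * rng.normal()))
                rows.append(row)
                t_row = {
                    "cow_id": cow_id, "country": country, "wol": int(wol),
                    "noiseless_dmi": noiseless, "u": u, "bw": bw,
                    "fat": fat, "protein": protein, "lactose": lactose,
                }
                for name in FA_PANEL:
                    t_row["fa_" + fa_slug(name)[4:]] = fa[name]
                truth_rows.append(t_row)

    records = pd.DataFrame(rows)
    spec_df = pd.DataFrame(np.asarray(spectra),
                           columns=[spectral_col(w) for w in grid])
    records = pd.concat([records, spec_df], axis=1)
    truth = GroundTruth(
        records=pd.DataFrame(truth_rows),
        coefficients=coef,
        country_offsets=offsets,
        bands=bands,
        component_names=comp_names,
        grid=grid,
    )
    return records, truth


def inject_spectral_outliers(records: pd.DataFrame, fraction: float,
                             magnitude: float, seed: int = 0):
    """Shift a random subset of spectra to make them GH-detectable.

    The shift is ``magnitude`` times the per-wavenumber SD of the clean
    spectra, signed by the leading principal direction, so an injected
    record moves many score-SDs both along and out of the clean
    high-variance subspace.  Returns ``(records', sorted outlier index
    array)``; indices are positions in the (reset) row order.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    records = records.reset_index(drop=True)
    n = len(records)
    n_out = int(round(fraction * n))
    if n_out == 0:
        return records.copy(), np.array([], dtype=int)
    from .records import spectral_columns, spectral_matrix
    X = spectral_matrix(records)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    v1 = Vt[0]
    if v1.sum() < 0:
        v1 = -v1
    sd = X.std(axis=0, ddof=1)
    shift = magnitude * sd * np.where(v1 >= 0, 1.0, -1.0)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_out, replace=False))
    out = records.copy()
    cols = spectral_columns(records)
    block = out.loc[idx, cols].to_numpy(float) + shift
    out.loc[idx, cols] = block
    return out, idx
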