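"""NRC (2001) dry matter intake baseline.

The National Research Council's non-linear equation predicts DMI (kg/d)
from 4%-fat-corrected milk yield (FCM, kg/d), metabolic bodyweight
(BW^0.75, kg) and week of lactation:

    DMI = (0.372 * FCM + 0.0968 * BW^0.75) * (1 - exp(-0.192 * (WOL + 3.67)))

with FCM = 0.4 * MY + 15 * fat yield.  The lag term ramps intake up from
calving toward the asymptote 0.372*FCM + 0.0968*BW^0.75.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .evaluation import rmse

# NRC (2001) coefficients, kept together so they can be audited against the
# source text.
FCM_MY_COEF = 0.4          # kg FCM per kg milk
FCM_FAT_COEF = 15.0        # kg FCM per kg milk fat
NRC_FCM_COEF = 0.372       # kg DMI per kg FCM
NRC_MBW_COEF = 0.0968      # kg DMI per kg metabolic bodyweight
NRC_WOL_RATE = 0.192       # 1/week, lactation ramp rate
NRC_WOL_LAG = 3.67         # weeks, ramp offset


@dataclasses.dataclass
class NRCInputs:
    fcm: float   # 4%-fat-corrected milk, kg/d
    bw: float    # bodyweight, kg
    wol: float   # week of lactation

    def __post_init__(self):
        if np.any(np.asarray(self.fcm) < 0):
            raise ValueError("FCM must be >= 0")
        if np.any(np.asarray(self.bw) <= 0):
            raise ValueError("bodyweight must be > 0")
        if np.any(np.asarray(self.wol) <= 0):
            raise ValueError("week of lactation must be > 0")


def fcm4(my, fat_pct):
    """4%-fat-corrected milk yield: 0.4*MY + 15*(MY*fat%/100), kg/d."""
    my = np.asarray(my, dtype=float)
    fat_pct = np.asarray(fat_pct, dtype=float)
    if np.any(my < 0) or np.any(fat_pct < 0):
        raise ValueError("milk yield and fat content must be >= 0")
    out = FCM_MY_COEF * my + FCM_FAT_COEF * (my * fat_pct / 100.0)
    return out if out.ndim else float(out)


def nrc_dmi(inputs: NRCInputs | None = None, *, fcm=None, bw=None, wol=None):
    """Evaluate the NRC-2001 DMI equation (kg/d)."""
    if inputs is not None:
        fcm, bw, wol = inputs.fcm, inputs.bw, inputs.wol
    fcm = np.asarray(fcm, dtype=float)
    bw = np.asarray(bw, dtype=float)
    wol = np.asarray(wol, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("bodyweight must be > 0")
    out = (NRC_FCM_COEF * fcm + NRC_MBW_COEF * bw**0.75) * (
        1.0 - np.exp(-NRC_WOL_RATE * (wol + NRC_WOL_LAG))
    )
    return out if out.ndim else float(out)


def nrc_predict(records: pd.DataFrame, fat: str = "pfat",
                bw: str = "pbw") -> np.ndarray:
    """NRC-2001 prediction for each record, with FCM from milk yield and
    the (MIR-predicted) fat content in g/dL, and the (predicted) bodyweight."""
    for col in ("my", "wol", fat, bw):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    fcm = fcm4(records["my"].to_numpy(float), records[fat].to_numpy(float))
    return nrc_dmi(fcm=fcm, bw=records[bw].to_numpy(float),
                   wol=records["wol"].to_numpy(float))


def nrc_rmse_on(records: pd.DataFrame, fat: str = "pfat",
                bw: str = "pbw") -> float:
    """RMSE of the NRC-2001 equation against measured DMI."""
    if "dmi" not in records.columns:
        raise ValueError("records lack column 'dmi'")
    return rmse(records["dmi"], nrc_predict(records, fat=fat, bw=bw))
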