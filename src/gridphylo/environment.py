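"""Per-cell climate and habitat-heterogeneity indices.

From twelve monthly mean temperatures (MT, °C) and precipitations (MP, mm)
per cell this module derives the fifteen predictors used downstream:

* energy availability — MAT, MTCM, MTWM, WI (Kira warmth index), CI (Kira
  coldness index, non-negative magnitude), PET (Thornthwaite);
* water availability — AP, RAIN (precipitation of months with MT > 0 °C),
  AET (Thornthwaite–Mather soil-water bucket);
* climatic stability — ART (= MTWM − MTCM), TSN and PSN (sample SD of the
  monthly series);
* habitat heterogeneity — TOPO (within-cell elevational range), VT (number of
  vegetation types present) and SWV (Shannon–Wiener entropy, natural log, of
  vegetation area fractions).

The Thornthwaite equations treat months with MT ≤ 0 °C as contributing zero
evaporative demand; the AET bucket is spun up by repeating the year until the
carried-over soil storage converges, so the reported AET is the equilibrium
annual total.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "annual_summaries",
    "warmth_rain_cold",
    "thornthwaite_pet",
    "water_balance_aet",
    "heterogeneity",
    "compute_environment",
    "ENV_COLUMNS",
]

ENV_COLUMNS = [
    "MAT", "MTCM", "MTWM", "CI", "WI", "PET", "AET",
    "AP", "RAIN", "ART", "TSN", "PSN", "TOPO", "VT", "SWV",
]

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
# mid-month day-of-year used for the solar declination of each month
_MID_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], dtype=float)


def _validate_months(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.shape != (12,):
        raise ValueError(f"{name} must have exactly 12 monthly values, got shape {a.shape}")
    if np.isnan(a).any():
        raise ValueError(f"{name} contains missing months")
    return a


def annual_summaries(mt, mp) -> dict[str, float]:
    """MAT, MTCM, MTWM, AP, ART and the seasonality SDs (sample SD, n-1)."""
    mt = _validate_months(mt, "MT")
    mp = _validate_months(mp, "MP")
    if (mp < 0).any():
        raise ValueError("monthly precipitation must be non-negative")
    return {
        "MAT": float(mt.mean()),
        "MTCM": float(mt.min()),
        "MTWM": float(mt.max()),
        "AP": float(mp.sum()),
        "ART": float(mt.max() - mt.min()),
        "TSN": float(mt.std(ddof=1)),
        "PSN": float(mp.std(ddof=1)),
    }


def warmth_rain_cold(mt, mp) -> dict[str, float]:
    """Kira indices and liquid-phase precipitation.

    WI = Σ (MT−5) over months with MT > 5 °C;
    CI = Σ (5−MT) over months with MT < 5 °C (non-negative magnitude: larger
    CI means a colder winter);
    RAIN = Σ MP over months with MT > 0 °C.
    """
    mt = _validate_months(mt, "MT")
    mp = _validate_months(mp, "MP")
    wi = float(np.sum(mt[mt > 5.0] - 5.0))
    ci = float(np.sum(5.0 - mt[mt < 5.0]))
    rain = float(np.sum(mp[mt > 0.0]))
    return {"WI": wi, "CI": ci, "RAIN": rain}


def _daylength_hours(latitude: float) -> np.ndarray:
    """Mean daylight hours per month (mid-month solar declination)."""
    phi = math.radians(latitude)
    decl = 0.409 * np.sin(2.0 * np.pi * _MID_DOY / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(x)
    return 24.0 / np.pi * omega


def thornthwaite_pet(mt, latitude: float) -> tuple[np.ndarray, float]:
    """Monthly and annual potential evapotranspiration (mm), Thornthwaite.

    I = Σ (MT_m/5)^1.514 over months with MT_m > 0;
    α = 6.75e-7 I³ − 7.71e-5 I² + 1.792e-2 I + 0.49239;
    PET_m = 16 (L_m/12)(N_m/30)(10 MT_m / I)^α for MT_m > 0, else 0,
    with L_m the mean daylength and N_m the number of days in month m.
    A cell frozen all year has PET = 0.
    """
    mt = _validate_months(mt, "MT")
    if abs(latitude) > 66.5:
        raise ValueError("latitude beyond polar circle: daylength correction invalid")
    warm = mt > 0.0
    if not warm.any():
        return np.zeros(12), 0.0
    heat_index = float(np.sum((mt[warm] / 5.0) ** 1.514))
    alpha = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    corr = (_daylength_hours(latitude) / 12.0) * (_MONTH_DAYS / 30.0)
    pet = np.zeros(12)
    pet[warm] = 16.0 * corr[warm] * (10.0 * mt[warm] / heat_index) ** alpha
    return pet, float(pet.sum())


def water_balance_aet(mp, pet_monthly, soil_capacity: float = 100.0,
                      tol: float = 0.01, max_years: int = 100,
                      initial_storage: float | None = None) -> float:
    """Annual actual evapotranspiration from a monthly soil-water bucket.

    In a surplus month (MP ≥ PET) the full demand is met and the excess
    recharges storage up to ``soil_capacity``.  In a deficit month the soil
    dries exponentially, ``W ← W·exp(−(PET−MP)/capacity)``, and AET is the
    precipitation plus the storage draw-down.  By default the 12-month ledger
    is repeated (starting from a full bucket) until the year-start storage
    changes by less than ``tol`` mm, and the converged year's AET total is
    returned; passing ``initial_storage`` instead runs a single year from that
    storage (useful for step-by-step checks).  Always AET_m ≤ PET_m.
    """
    if soil_capacity <= 0:
        raise ValueError("soil_capacity must be strictly positive")
    mp = _validate_months(mp, "MP")
    pet = _validate_months(pet_monthly, "PET")
    if initial_storage is not None:
        w = float(initial_storage)
        max_years = 1
        tol = math.inf
    else:
        w = soil_capacity
    annual = 0.0
    for _ in range(max_years):
        w0 = w
        annual = 0.0
        for m in range(12):
            if mp[m] >= pet[m]:
                aet = pet[m]
                w = min(soil_capacity, w + mp[m] - pet[m])
            else:
                w_new = w * math.exp(-(pet[m] - mp[m]) / soil_capacity)
                aet = mp[m] + (w - w_new)
                w = w_new
            annual += aet
        if abs(w - w0) < tol:
            break
    return float(annual)


def heterogeneity(elev_min: float, elev_max: float, fractions) -> dict[str, float]:
    """TOPO, VT and the Shannon–Wiener vegetation entropy SWV (nats).

    ``fractions`` are the area fractions P_i of the vegetation types within
    the cell; they must sum to 1 (tolerance 1e-6).  Zero fractions contribute
    nothing to SWV.
    """
    p = np.asarray(list(fractions), dtype=float)
    if (p < 0).any():
        raise ValueError("vegetation fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"vegetation fractions sum to {p.sum():.8f}, expected 1")
    pos = p[p > 0]
    swv = float(-(pos * np.log(pos)).sum())
    return {
        "TOPO": float(elev_max) - float(elev_min),
        "VT": int((p > 0).sum()),
        "SWV": swv,
    }


def compute_environment(
    climate: pd.DataFrame,
    grid: pd.DataFrame,
    vegetation: pd.DataFrame,
    soil_capacity: float = 100.0,
) -> pd.DataFrame:
    """Assemble the full 15-column environment table, one row per cell.

    ``climate`` has columns (cell, month, MT, MP); ``grid`` has (cell,
    lat_mid, elev_min, elev_max); ``vegetation`` has (cell, type, fraction).
    """
    grid = grid.set_index("cell")
    rows = {}
    for cell, sub in climate.groupby("cell", sort=False):
        sub = sub.sort_values("month")
        mt = sub["MT"].to_numpy()
        mp = sub["MP"].to_numpy()
        rec = annual_summaries(mt, mp)
        rec.update(warmth_rain_cold(mt, mp))
        pet_m, pet = thornthwaite_pet(mt, float(grid.loc[cell, "lat_mid"]))
        rec["PET"] = pet
        rec["AET"] = water_balance_aet(mp, pet_m, soil_capacity)
        rows[cell] = rec
    for cell, sub in vegetation.groupby("cell", sort=False):
        rows[cell].update(
            heterogeneity(
                grid.loc[cell, "elev_min"],
                grid.loc[cell, "elev_max"],
                sub["fraction"].to_numpy(),
            )
        )
    env = pd.DataFrame.from_dict(rows, orient="index")[ENV_COLUMNS]
    env.index.name = "cell"
    return env
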