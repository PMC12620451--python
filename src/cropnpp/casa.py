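"""CASA light-use-efficiency model for monthly crop NPP.

The Carnegie–Ames–Stanford Approach computes net primary productivity as

    NPP(x, t) = APAR(x, t) * eps(x, t)
    APAR(x, t) = SOL(x, t) * FPAR(x, t) * 0.5
    eps(x, t)  = Te1(x) * Te2(x, t) * We(x, t) * eps_max

where SOL is monthly total solar radiation (MJ/m^2/month), FPAR the
fraction of absorbed photosynthetically active radiation, the factor 0.5
the PAR fraction of shortwave radiation, and eps_max the maximum
light-use efficiency (default 0.389 gC/MJ for crops).

The stress scalars follow the standard regional-CASA formulations:

* low-temperature stress  Te1 = 0.8 + 0.02*Topt - 0.0005*Topt^2,
  zeroed in months whose mean temperature is at or below -10 degC;
* high/low excursion stress
  Te2 = 1.1814 / ((1 + exp(0.2*(Topt - 10 - T))) * (1 + exp(0.3*(-Topt - 10 + T))));
* water stress  We = 0.5 + 0.5 * EET/PET, with estimated
  evapotranspiration EET = min(P, PET) by default and PET from the
  Thornthwaite monthly formulation. Externally computed EET/PET grids
  may be supplied instead.

Topt, the optimal growth temperature, is the mean temperature of the
month in which the NDVI seasonal profile peaks.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np

from .errors import MissingMonthError, NegativePrecipitationError, ShapeMismatchError
from .grids import Grid, check_aligned

#: Default maximum light-use efficiency for crops, gC/MJ.
DEFAULT_EPSILON_MAX = 0.389

#: Default growing season, April through October inclusive.
SEASON_MONTHS = tuple(range(4, 11))


@dataclass
class MeteoGrid:
    """Model-ready monthly meteorology for one month.

    sol: total solar radiation, MJ/m^2/month; temp: monthly mean
    temperature, degC; precip: monthly precipitation, mm.
    """

    sol: Grid
    temp: Grid
    precip: Grid
    month: int

    def __post_init__(self) -> None:
        check_aligned(self.sol, self.temp, self.precip)
        if not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if np.any(self.sol.valid_values() < 0):
            raise ValueError("solar radiation must be non-negative")
        if np.any(self.precip.valid_values() < 0):
            raise NegativePrecipitationError("precipitation must be non-negative")


@dataclass
class StressParams:
    """Stress-model parameters: Topt (degC, grid or scalar) and eps_max."""

    topt: Grid | float = 20.0
    epsilon_max: float = DEFAULT_EPSILON_MAX

    def __post_init__(self) -> None:
        if self.epsilon_max <= 0:
            raise ValueError("epsilon_max must be > 0")


@dataclass
class NppGrid:
    """Monthly and seasonal NPP, gC/m^2, with provenance of the FPAR source."""

    monthly: dict[int, Grid]
    annual: Grid
    provenance: str = "cnn"


def _as_array(x, shape) -> np.ndarray:
    if isinstance(x, Grid):
        return x.values
    return np.broadcast_to(np.asarray(x, dtype=float), shape)


def compute_apar(sol: Grid, fpar: Grid) -> Grid:
    """Absorbed PAR: APAR = SOL * FPAR * 0.5 (MJ/m^2/month)."""
    check_aligned(sol, fpar)
    return sol.with_values(sol.values * fpar.values * 0.5, fpar.mask)


def temp_stress_low(topt, temp: Grid | None = None) -> np.ndarray:
    """Low-temperature stress Te1, clamped to [0, 1].

    Te1 = 0.8 + 0.02*Topt - 0.0005*Topt^2. Where the monthly mean
    temperature is at or below -10 degC the month is treated as frozen
    and Te1 = 0.
    """
    t = np.asarray(topt.values if isinstance(topt, Grid) else topt, dtype=float)
    te1 = np.clip(0.8 + 0.02 * t - 0.0005 * t * t, 0.0, 1.0)
    if temp is not None:
        tm = temp.values if isinstance(temp, Grid) else np.asarray(temp, float)
        te1 = np.where(tm <= -10.0, 0.0, te1)
    return te1


def temp_stress_high(temp: Grid, topt) -> np.ndarray:
    """Temperature-excursion stress Te2, clamped to [0, 1].

    Double-logistic form with the 1.1814 normalizer; peaks near T = Topt
    (value ~0.9914) and decays toward 0 for cold or hot months.
    """
    t = temp.values if isinstance(temp, Grid) else np.asarray(temp, float)
    to = _as_array(topt, np.shape(t))
    with np.errstate(over="ignore"):
        te2 = 1.1814 / ((1.0 + np.exp(0.2 * (to - 10.0 - t)))
                        * (1.0 + np.exp(0.3 * (-to - 10.0 + t))))
    return np.clip(te2, 0.0, 1.0)


def thornthwaite_pet(monthly_temp: dict[int, Grid | float], year: int = 2022,
                     ) -> dict[int, np.ndarray]:
    """Monthly potential evapotranspiration (mm) via Thornthwaite.

    heat index I = sum over months of (T/5)^1.514 for T > 0;
    exponent alpha = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239;
    PET = 16 * (10 T / I)^alpha * days_in_month/30 for T > 0, else 0.
    A 12-hour day length is assumed (no latitude correction).
    """
    temps = {m: np.asarray(v.values if isinstance(v, Grid) else v, dtype=float)
             for m, v in monthly_temp.items()}
    shape = np.broadcast_shapes(*(np.shape(v) for v in temps.values()))
    heat = np.zeros(shape)
    for v in temps.values():
        tv = np.broadcast_to(v, shape)
        heat = heat + np.where(tv > 0, (np.maximum(tv, 0.0) / 5.0) ** 1.514, 0.0)
    heat = np.maximum(heat, 1e-9)
    alpha = 6.75e-7 * heat ** 3 - 7.71e-5 * heat ** 2 + 1.792e-2 * heat + 0.49239
    pet = {}
    for m, v in temps.items():
        tv = np.broadcast_to(v, shape)
        days = calendar.monthrange(year, m)[1]
        base = 16.0 * (10.0 * np.maximum(tv, 0.0) / heat) ** alpha
        pet[m] = np.where(tv > 0, base * days / 30.0, 0.0)
    return pet


def water_stress(precip: Grid, pet: np.ndarray | Grid) -> np.ndarray:
    """Water stress We = 0.5 + 0.5 * EET/PET, in [0.5, 1].

    EET = min(P, PET); where PET = 0 (no atmospheric demand) We = 1.
    """
    p = precip.values if isinstance(precip, Grid) else np.asarray(precip, float)
    if np.any(p[np.isfinite(p)] < 0):
        raise NegativePrecipitationError("precipitation must be non-negative")
    pe = pet.values if isinstance(pet, Grid) else np.asarray(pet, float)
    eet = np.minimum(p, pe)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pe > 0, eet / np.where(pe > 0, pe, 1.0), 1.0)
    return 0.5 + 0.5 * np.clip(ratio, 0.0, 1.0)


def actual_lue(te1, te2, we, params: StressParams) -> np.ndarray:
    """Actual light-use efficiency eps = Te1*Te2*We*eps_max, in [0, eps_max]."""
    eps = np.asarray(te1, float) * np.asarray(te2, float) * np.asarray(we, float)
    return np.clip(eps, 0.0, 1.0) * params.epsilon_max


def monthly_npp(apar: Grid, eps) -> Grid:
    """Monthly NPP = APAR * eps, gC/m^2/month, clipped non-negative."""
    e = _as_array(eps, apar.shape)
    if np.shape(e) != apar.shape:
        raise ShapeMismatchError("eps grid shape differs from APAR")
    return apar.with_values(np.maximum(apar.values * e, 0.0))


def season_npp(monthly: dict[int, Grid], season: tuple[int, ...] = SEASON_MONTHS,
               policy: str = "strict") -> Grid:
    """Sum monthly NPP over the growing season.

    policy='strict' masks a pixel in the seasonal total if it is masked
    in any month; policy='partial' sums whatever months are valid.
    """
    missing = [m for m in season if m not in monthly]
    if missing:
        raise MissingMonthError(f"missing months for seasonal sum: {missing}")
    grids = [monthly[m] for m in season]
    check_aligned(*grids)
    total = np.zeros(grids[0].shape)
    any_valid = np.zeros(grids[0].shape, dtype=bool)
    all_valid = np.ones(grids[0].shape, dtype=bool)
    for g in grids:
        total += np.where(g.mask, 0.0, g.values)
        any_valid |= g.valid
        all_valid &= g.valid
    mask = ~all_valid if policy == "strict" else ~any_valid
    return Grid(total, mask, grids[0].transform, grids[0].crs)


def estimate_topt(ndvi_by_month: dict[int, Grid], temp_by_month: dict[int, Grid]) -> Grid:
    """Optimal temperature: mean T of the month of peak NDVI, per pixel.

    Ties (including constant NDVI series) resolve to the earliest month.
    """
    months = sorted(ndvi_by_month)
    if not months:
        raise MissingMonthError("empty NDVI series")
    for m in months:
        if m not in temp_by_month:
            raise MissingMonthError(f"temperature missing for month {m}")
    ndvi_stack = np.stack([ndvi_by_month[m].values for m in months])
    ndvi_stack = np.where(np.isfinite(ndvi_stack), ndvi_stack, -np.inf)
    peak = np.argmax(ndvi_stack, axis=0)  # argmax takes the first maximum
    temp_stack = np.stack([temp_by_month[m].values for m in months])
    topt = np.take_along_axis(temp_stack, peak[None], axis=0)[0]
    ref = ndvi_by_month[months[0]]
    return Grid(topt, ref.mask.copy(), ref.transform, ref.crs)


def run_casa(fpar_by_month: dict[int, Grid], meteo_by_month: dict[int, MeteoGrid],
             params: StressParams, season: tuple[int, ...] = SEASON_MONTHS,
             provenance: str = "cnn", policy: str = "strict",
             pet_by_month: dict[int, np.ndarray] | None = None) -> NppGrid:
    """Full CASA run: monthly NPP for each season month plus the seasonal sum.

    PET defaults to Thornthwaite from all months of meteorology supplied
    (ideally a full year, so the heat index is annual).
    """
    missing = [m for m in season if m not in fpar_by_month or m not in meteo_by_month]
    if missing:
        raise MissingMonthError(f"missing inputs for months: {missing}")
    if pet_by_month is None:
        pet_by_month = thornthwaite_pet({m: mg.temp for m, mg in meteo_by_month.items()})
    monthly: dict[int, Grid] = {}
    for m in season:
        mg = meteo_by_month[m]
        fpar = fpar_by_month[m]
        apar = compute_apar(mg.sol, fpar)
        te1 = temp_stress_low(params.topt, mg.temp)
        te2 = temp_stress_high(mg.temp, params.topt)
        we = water_stress(mg.precip, pet_by_month[m])
        eps = actual_lue(te1, te2, we, params)
        monthly[m] = monthly_npp(apar, eps)
    annual = season_npp(monthly, season, policy=policy)
    return NppGrid(monthly=monthly, annual=annual, provenance=provenance)
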