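"""Station meteorology to model-ready monthly grids.

Covers the two preprocessing steps the NPP model needs: converting daily
solar-radiation records (J/m^2/day) to monthly totals (MJ/m^2/month),
and spatially interpolating station values onto the analysis grid by
ordinary kriging (exponential variogram fitted by weighted least
squares) with an inverse-distance-weighting fallback for very small
station networks.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TooFewStationsError
from .grids import Grid


@dataclass
class StationRecord:
    """One station-month meteorology record."""

    station_id: str
    lon: float
    lat: float
    month: int
    sol_monthly: float  # MJ/m^2/month
    temp_mean: float  # degC
    precip: float  # mm


def convert_radiation(daily_value: float | np.ndarray, month: int,
                      year: int = 2022) -> float | np.ndarray:
    """Convert J/m^2/day to MJ/m^2/month: value * days_in_month / 1e6."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    days = calendar.monthrange(year, month)[1]
    out = np.asarray(daily_value, dtype=float) * days / 1e6
    return float(out) if np.isscalar(daily_value) else out


def read_station_csv(path) -> list[StationRecord]:
    """Read a station table (station_id, lon, lat, month, sol, temp, precip).

    Accepts either a ``sol_monthly`` column (MJ/m^2/month) or a
    ``sol_daily`` column (J/m^2/day), converting the latter.
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        month = int(row["month"])
        if "sol_monthly" in df.columns and pd.notna(row.get("sol_monthly")):
            sol = float(row["sol_monthly"])
        else:
            sol = convert_radiation(float(row["sol_daily"]), month)
        records.append(StationRecord(
            station_id=str(row["station_id"]), lon=float(row["lon"]),
            lat=float(row["lat"]), month=month, sol_monthly=sol,
            temp_mean=float(row["temp_mean"]), precip=float(row["precip"])))
    return records


def write_station_csv(records: list[StationRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interpolation


def _cell_centers(template: Grid) -> tuple[np.ndarray, np.ndarray]:
    a, b, c, d, e, f = template.transform
    rows, cols = np.mgrid[0:template.shape[0], 0:template.shape[1]]
    cc, rr = cols + 0.5, rows + 0.5
    return a * cc + b * rr + c, d * cc + e * rr + f


def _idw(sx, sy, sv, px, py, power: float = 2.0) -> np.ndarray:
    d2 = (px[:, None] - sx[None, :]) ** 2 + (py[:, None] - sy[None, :]) ** 2
    out = np.empty(px.shape[0])
    exact = d2 < 1e-24
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.where(d2 == 0, np.inf, d2) ** (power / 2.0)
    wsum = w.sum(axis=1)
    out = (w @ sv) / np.where(wsum == 0, 1.0, wsum)
    if has_exact.any():
        first = np.argmax(exact, axis=1)
        out[has_exact] = sv[first[has_exact]]
    return out


def fit_exponential_variogram(sx, sy, sv, n_bins: int = 8,
                              nugget: float = 0.0) -> tuple[float, float, float]:
    """Fit gamma(h) = nugget + sill*(1 - exp(-h/range)) to the empirical
    semivariogram by weighted least squares (weights = pair counts).

    Returns (nugget, sill, range). With very few stations the fit falls
    back to sample variance and one-third of the maximum separation.
    """
    n = sv.size
    dx = sx[:, None] - sx[None, :]
    dy = sy[:, None] - sy[None, :]
    h = np.sqrt(dx * dx + dy * dy)
    iu = np.triu_indices(n, 1)
    hv, gv = h[iu], 0.5 * (sv[:, None] - sv[None, :])[iu] ** 2
    hmax = float(hv.max()) if hv.size else 1.0
    sill0 = max(float(np.var(sv)), 1e-12)
    rng0 = max(hmax / 3.0, 1e-12)
    if hv.size < n_bins:
        return nugget, sill0, rng0
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, means, counts = [], [], []
    for i in range(n_bins):
        sel = (hv > edges[i]) & (hv <= edges[i + 1])
        if sel.sum() > 0:
            centers.append(0.5 * (edges[i] + edges[i + 1]))
            means.append(float(gv[sel].mean()))
            counts.append(int(sel.sum()))
    if len(centers) < 3:
        return nugget, sill0, rng0
    centers, means, counts = map(np.asarray, (centers, means, counts))

    from scipy.optimize import least_squares

    def resid(theta):
        sill, rg = np.exp(theta)
        return np.sqrt(counts) * (nugget + sill * (1 - np.exp(-centers / rg)) - means)

    try:
        sol = least_squares(resid, np.log([sill0, rng0]), max_nfev=200)
        sill, rg = np.exp(sol.x)
        if not (np.isfinite(sill) and np.isfinite(rg)) or sill <= 0 or rg <= 0:
            raise ValueError
        return nugget, float(sill), float(rg)
    except Exception:
        return nugget, sill0, rng0


def _kriging(sx, sy, sv, px, py, nugget: float, sill: float, rng: float):
    n = sv.size

    def gamma(h):
        g = nugget + sill * (1.0 - np.exp(-h / rng))
        return np.where(h == 0, 0.0, g)  # gamma(0)=0 even with a nugget model

    dx = sx[:, None] - sx[None, :]
    dy = sy[:, None] - sy[None, :]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = gamma(np.sqrt(dx * dx + dy * dy))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    d0 = np.sqrt((px[:, None] - sx[None, :]) ** 2 + (py[:, None] - sy[None, :]) ** 2)
    B = np.ones((n + 1, px.size))
    B[:n, :] = gamma(d0).T
    weights = np.linalg.solve(A, B)  # raises LinAlgError if singular
    return weights[:n, :].T @ sv


def interpolate_grid(stations: list[StationRecord], variable: str,
                     template: Grid, method: str = "kriging",
                     variogram: tuple[float, float, float] | None = None) -> Grid:
    """Interpolate one station variable onto the template grid.

    variable is one of 'sol', 'temp', 'precip'. Kriging needs >= 3
    stations; IDW needs >= 1. A singular kriging system (e.g. duplicate
    station locations) falls back to IDW with a warning.
    """
    attr = {"sol": "sol_monthly", "temp": "temp_mean", "precip": "precip"}[variable]
    sx = np.array([s.lon for s in stations], dtype=float)
    sy = np.array([s.lat for s in stations], dtype=float)
    sv = np.array([getattr(s, attr) for s in stations], dtype=float)
    if method == "kriging" and sv.size < 3:
        raise TooFewStationsError(f"kriging needs >= 3 stations, got {sv.size}")
    if sv.size < 1:
        raise TooFewStationsError("no stations supplied")
    gx, gy = _cell_centers(template)
    px, py = gx.ravel(), gy.ravel()
    if method == "kriging":
        nugget, sill, rng = (variogram if variogram is not None
                             else fit_exponential_variogram(sx, sy, sv))
        try:
            vals = _kriging(sx, sy, sv, px, py, nugget, sill, rng)
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system; falling back to IDW", stacklevel=2)
            vals = _idw(sx, sy, sv, px, py)
    elif method == "idw":
        vals = _idw(sx, sy, sv, px, py)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return Grid(vals.reshape(template.shape), template.mask.copy(),
                template.transform, template.crs)
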