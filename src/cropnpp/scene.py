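"""Synthetic crop-scene generator: a self-contained test world.

Builds seasonal multispectral reflectance, station-style meteorology and
ground-truth FPAR/NPP with the statistical structure the retrieval
pipeline assumes:

* per-class leaf area index (LAI) follows a double-logistic seasonal
  curve (green-up and senescence logistics), modulated by a smooth
  per-pixel heterogeneity field;
* FPAR follows Beer-Lambert extinction, FPAR = 1 - exp(-k * LAI) with
  k = 0.5 by default;
* band reflectance is a linear mixture of canopy and soil endmembers
  weighted by FPAR (used as fractional cover), plus independent
  Gaussian band noise;
* meteorology is a seasonal sinusoid matching configured annual
  statistics (defaults: 9.3 degC mean temperature, 710.2 mm annual
  precipitation, summer-peaking radiation);
* true NPP is the CASA forward model run on the true FPAR and the scene
  meteorology, so forward self-consistency holds by construction.

Cloud contamination is observational: injected patches corrupt the
reflectance (bright, spectrally flat) and are flagged, while the stored
truth is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import casa
from .casa import MeteoGrid, NppGrid, StressParams
from .grids import BAND_NAMES, Grid, ReflectanceStack
from .meteo import StationRecord

ALL_MONTHS = tuple(range(1, 13))

#: Default linear-mixture endmembers per band (surface reflectance).
SOIL_ENDMEMBERS = {"B2": 0.10, "B3": 0.13, "B4": 0.20, "B5": 0.23,
                   "B6": 0.25, "B7": 0.27, "B8": 0.30, "B8A": 0.31}
CANOPY_ENDMEMBERS = {"B2": 0.03, "B3": 0.06, "B4": 0.04, "B5": 0.12,
                     "B6": 0.30, "B7": 0.40, "B8": 0.45, "B8A": 0.46}


@dataclass(frozen=True)
class LaiCurve:
    """Double-logistic seasonal LAI: green-up and senescence logistics."""

    peak_lai: float
    green_up: float  # month of green-up inflection
    senescence: float  # month of senescence inflection
    rate: float = 2.0

    def value(self, month: float | np.ndarray) -> np.ndarray:
        m = np.asarray(month, dtype=float)
        g = (1.0 / (1.0 + np.exp(-self.rate * (m - self.green_up)))
             * 1.0 / (1.0 + np.exp(self.rate * (m - self.senescence))))
        fine = np.linspace(1, 12, 241)
        gmax = np.max(1.0 / (1.0 + np.exp(-self.rate * (fine - self.green_up)))
                      * 1.0 / (1.0 + np.exp(self.rate * (fine - self.senescence))))
        return self.peak_lai * g / max(gmax, 1e-12)


DEFAULT_CURVES = {
    "rice": LaiCurve(peak_lai=5.5, green_up=5.5, senescence=9.8),
    "corn": LaiCurve(peak_lai=5.0, green_up=5.8, senescence=9.5),
    "forest": LaiCurve(peak_lai=5.5, green_up=4.5, senescence=10.5, rate=1.5),
    "soil": LaiCurve(peak_lai=0.0, green_up=6.0, senescence=9.0),
}


@dataclass
class CloudConfig:
    months: tuple[int, ...] = (7, 8)
    patch_fraction: float = 0.15
    patch_reflectance: float = 0.6  # bright, spectrally flat


@dataclass
class MeteoConfig:
    """Seasonal-sinusoid climatology (annual statistics are exact)."""

    annual_mean_temp: float = 9.3  # degC
    temp_amplitude: float = 15.0
    annual_precip: float = 710.2  # mm/year
    precip_concentration: float = 1.5  # von-Mises-like summer weighting
    sol_mean: float = 400.0  # MJ/m^2/month
    sol_amplitude: float = 250.0
    warm_peak_month: float = 7.0


@dataclass
class SceneConfig:
    shape: tuple[int, int] = (40, 40)
    pixel_size: float = 10.0  # metres
    crop_fractions: dict = field(default_factory=lambda: {
        "rice": 0.35, "corn": 0.35, "forest": 0.15, "soil": 0.15})
    season: tuple[int, ...] = casa.SEASON_MONTHS
    lai_curves: dict = field(default_factory=lambda: dict(DEFAULT_CURVES))
    extinction_k: float = 0.5
    soil_endmembers: dict = field(default_factory=lambda: dict(SOIL_ENDMEMBERS))
    canopy_endmembers: dict = field(default_factory=lambda: dict(CANOPY_ENDMEMBERS))
    noise_sigma: float = 0.005
    heterogeneity: float = 0.15  # relative spread of the per-pixel LAI scale
    cloud: CloudConfig = field(default_factory=CloudConfig)
    meteo: MeteoConfig = field(default_factory=MeteoConfig)
    epsilon_max: float = casa.DEFAULT_EPSILON_MAX
    crs: str = "local-metric"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.crop_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"crop fractions must sum to 1, got {total}")
        unknown = set(self.crop_fractions) - set(self.lai_curves)
        if unknown:
            raise ValueError(f"no LAI curve for classes: {sorted(unknown)}")
        if self.extinction_k <= 0:
            raise ValueError("extinction k must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class SceneTruth:
    """Everything the generator knows about one scene."""

    config: SceneConfig
    class_map: np.ndarray  # str array of class labels
    stacks: dict[int, ReflectanceStack]  # season months
    fpar: dict[int, Grid]  # true FPAR, season months
    lai: dict[int, np.ndarray]
    meteo: dict[int, MeteoGrid]  # all 12 months
    npp: NppGrid  # truth, via the CASA forward model
    stress_params: StressParams
    cloud_mask: dict[int, np.ndarray] = field(default_factory=dict)


def _class_map(cfg: SceneConfig) -> np.ndarray:
    """Contiguous vertical strips per class, in a fixed class order."""
    nrow, ncol = cfg.shape
    labels = np.empty((nrow, ncol), dtype=object)
    order = [c for c in ("rice", "corn", "forest", "soil") if c in cfg.crop_fractions]
    order += [c for c in cfg.crop_fractions if c not in order]
    start = 0
    for i, cls in enumerate(order):
        width = (round(sum(cfg.crop_fractions[c] for c in order[: i + 1]) * ncol)
                 - start)
        labels[:, start:start + width] = cls
        start += width
    labels[:, start:] = order[-1]
    return labels


def _smooth_field(rng: np.random.Generator, shape, rel_spread: float) -> np.ndarray:
    """Multiplicative heterogeneity field, smoothed white noise around 1."""
    from scipy.ndimage import gaussian_filter

    noise = rng.normal(0.0, 1.0, size=shape)
    smooth = gaussian_filter(noise, sigma=2.0, mode="reflect")
    sd = smooth.std() or 1.0
    return np.clip(1.0 + rel_spread * smooth / sd, 0.2, 2.0)


def monthly_meteo_values(mc: MeteoConfig, year: int = 2022) -> dict[int, dict]:
    """Scalar per-month climatology matching the configured annual stats."""
    months = np.arange(1, 13)
    phase = 2.0 * np.pi * (months - mc.warm_peak_month) / 12.0
    temp = mc.annual_mean_temp + mc.temp_amplitude * np.cos(phase)
    w = np.exp(mc.precip_concentration * np.cos(phase))
    precip = mc.annual_precip * w / w.sum()
    sol_phase = 2.0 * np.pi * (months - (mc.warm_peak_month - 0.5)) / 12.0
    sol = np.maximum(mc.sol_mean + mc.sol_amplitude * np.cos(sol_phase), 0.0)
    return {int(m): {"temp": float(temp[i]), "precip": float(precip[i]),
                     "sol": float(sol[i])}
            for i, m in enumerate(months)}


def generate_scene(cfg: SceneConfig | None = None) -> SceneTruth:
    """Generate a full scene; bit-reproducible from ``cfg.seed``."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    nrow, ncol = cfg.shape
    transform = (cfg.pixel_size, 0.0, 0.0, 0.0, -cfg.pixel_size, 0.0)
    labels = _class_map(cfg)
    hetero = _smooth_field(rng, cfg.shape, cfg.heterogeneity)

    # spatial gradients give the meteorology mild, smooth structure
    gx = np.linspace(-1.0, 1.0, ncol)[None, :] * np.ones((nrow, 1))
    gy = np.linspace(-1.0, 1.0, nrow)[:, None] * np.ones((1, ncol))
    climat = monthly_meteo_values(cfg.meteo)

    meteo: dict[int, MeteoGrid] = {}
    for m in ALL_MONTHS:
        c = climat[m]
        temp = Grid(c["temp"] + 0.3 * gx, transform=transform, crs=cfg.crs)
        precip = Grid(np.maximum(c["precip"] * (1.0 + 0.05 * gy), 0.0),
                      transform=transform, crs=cfg.crs)
        sol = Grid(np.maximum(c["sol"] * (1.0 + 0.02 * gx), 0.0),
                   transform=transform, crs=cfg.crs)
        meteo[m] = MeteoGrid(sol=sol, temp=temp, precip=precip, month=m)

    lai_by_month: dict[int, np.ndarray] = {}
    fpar: dict[int, Grid] = {}
    stacks: dict[int, ReflectanceStack] = {}
    for m in cfg.season:
        lai = np.zeros(cfg.shape)
        for cls, curve in cfg.lai_curves.items():
            sel = labels == cls
            if sel.any():
                lai[sel] = curve.value(float(m))
        lai *= hetero
        lai_by_month[m] = lai
        fp = 1.0 - np.exp(-cfg.extinction_k * lai)
        fpar[m] = Grid(fp, transform=transform, crs=cfg.crs)
        bands = {}
        for bn in BAND_NAMES:
            clean = (fp * cfg.canopy_endmembers[bn]
                     + (1.0 - fp) * cfg.soil_endmembers[bn])
            bands[bn] = clean + rng.normal(0.0, cfg.noise_sigma, size=cfg.shape)
        stacks[m] = ReflectanceStack(bands=bands, transform=transform,
                                     crs=cfg.crs, month=m)

    # Topt: temperature of the month of peak LAI (same rule the model uses)
    lai_stack = np.stack([lai_by_month[m] for m in cfg.season])
    peak = np.argmax(lai_stack, axis=0)
    temp_stack = np.stack([meteo[m].temp.values for m in cfg.season])
    topt = Grid(np.take_along_axis(temp_stack, peak[None], axis=0)[0],
                transform=transform, crs=cfg.crs)
    params = StressParams(topt=topt, epsilon_max=cfg.epsilon_max)

    npp = casa.run_casa(fpar, meteo, params, season=cfg.season,
                        provenance="truth")
    return SceneTruth(config=cfg, class_map=labels, stacks=stacks, fpar=fpar,
                      lai=lai_by_month, meteo=meteo, npp=npp,
                      stress_params=params,
                      cloud_mask={m: np.zeros(cfg.shape, bool) for m in cfg.season})


def inject_clouds(truth: SceneTruth, cloud: CloudConfig | None = None,
                  seed: int | None = None) -> SceneTruth:
    """Contaminate configured months with bright cloud patches.

    Reflectance in the patches is replaced by the (spectrally flat)
    cloud reflectance plus noise; the stored FPAR/NPP truth is
    untouched — contamination is observational.
    """
    cloud = cloud or truth.config.cloud
    rng = np.random.default_rng(truth.config.seed + 7919 if seed is None else seed)
    nrow, ncol = truth.config.shape
    stacks = dict(truth.stacks)
    cloud_mask = {m: mk.copy() for m, mk in truth.cloud_mask.items()}
    for m in cloud.months:
        if m not in stacks:
            continue
        flag = np.zeros((nrow, ncol), dtype=bool)
        target = cloud.patch_fraction * nrow * ncol
        if cloud.patch_fraction >= 1.0:
            flag[:] = True
        else:
            guard = 0
            while flag.sum() < target and guard < 1000:
                guard += 1
                h = int(rng.integers(2, max(3, nrow // 4)))
                w = int(rng.integers(2, max(3, ncol // 4)))
                r0 = int(rng.integers(0, max(1, nrow - h)))
                c0 = int(rng.integers(0, max(1, ncol - w)))
                flag[r0:r0 + h, c0:c0 + w] = True
        old = stacks[m]
        bands = {}
        for bn, arr in old.bands.items():
            new = arr.copy()
            new[flag] = (cloud.patch_reflectance
                         + rng.normal(0.0, truth.config.noise_sigma, size=int(flag.sum())))
            bands[bn] = new
        stacks[m] = ReflectanceStack(bands=bands, mask=old.mask.copy(),
                                     transform=old.transform, crs=old.crs,
                                     month=m)
        cloud_mask[m] = flag
    return SceneTruth(config=truth.config, class_map=truth.class_map,
                      stacks=stacks, fpar=truth.fpar, lai=truth.lai,
                      meteo=truth.meteo, npp=truth.npp,
                      stress_params=truth.stress_params, cloud_mask=cloud_mask)


def scene_station_records(truth: SceneTruth, n_stations: int = 6,
                          seed: int | None = None) -> list[StationRecord]:
    """Sample pseudo-stations from the scene's meteorology grids."""
    rng = np.random.default_rng(truth.config.seed + 104729 if seed is None else seed)
    nrow, ncol = truth.config.shape
    rows = rng.integers(0, nrow, size=n_stations)
    cols = rng.integers(0, ncol, size=n_stations)
    a, b, c, d, e, f = truth.meteo[1].sol.transform
    records = []
    for i, (r, cc) in enumerate(zip(rows, cols)):
        x = a * (cc + 0.5) + b * (r + 0.5) + c
        y = d * (cc + 0.5) + e * (r + 0.5) + f
        for m, mg in truth.meteo.items():
            records.append(StationRecord(
                station_id=f"S{i:02d}", lon=float(x), lat=float(y), month=m,
                sol_monthly=float(mg.sol.values[r, cc]),
                temp_mean=float(mg.temp.values[r, cc]),
                precip=float(mg.precip.values[r, cc])))
    return records


def scene_training_samples(truth: SceneTruth, months: list[int] | None = None,
                           n_samples: int | None = None,
                           seed: int | None = None):
    """Pooled (index-matrix, FPAR) training samples from clean scene months.

    Computes the 15 indices from the (noisy) reflectance and pairs each
    valid pixel with its true FPAR. Returns ``(FeatureMatrix, fpar_vector)``.
    """
    from .fpar import FeatureMatrix
    from .indices import INDEX_NAMES, compute_all

    months = list(months) if months is not None else list(truth.stacks)
    mats, ys = [], []
    for m in months:
        cube = compute_all(truth.stacks[m])
        mat, valid = cube.to_matrix(list(INDEX_NAMES))
        mats.append(mat)
        ys.append(truth.fpar[m].values[valid])
    X = np.vstack(mats)
    y = np.concatenate(ys)
    if n_samples is not None and n_samples < X.shape[0]:
        rng = np.random.default_rng(truth.config.seed + 65537 if seed is None else seed)
        idx = rng.choice(X.shape[0], size=n_samples, replace=False)
        X, y = X[idx], y[idx]
    return FeatureMatrix(X, list(INDEX_NAMES)), np.clip(y, 0.0, 1.0)
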