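"""The 15 vegetation indices used for FPAR retrieval.

Each index is an algebraic combination of Sentinel-2 band reflectances
(B2 blue, B3 green, B4 red, B5–B7 red edge, B8 NIR, B8A narrow NIR).
Soil-adjusted indices (PVI, SAVI, TSAVI, WDVI, MSAVI) additionally use
soil-line parameters: slope ``s``, intercept ``a``, soil-noise factor
``X`` and the SAVI calibration factor ``L``.

Conventions adopted for the formulas whose published typography is
ambiguous (documented in docs/methods.md):

* ARVI uses the atmospheric correction ``rb = 2*B4 - B2`` (gamma = 1):
  ``(B8 - rb) / (B8 + rb)``.
* MSAVI is the closed-form modified SAVI
  ``(2*B8 + 1 - sqrt((2*B8+1)^2 - 8*(B8-B4))) / 2``.
* TNDVI is ``sqrt(NDVI + 0.5)``, masked where the radicand is negative.
* GEMI uses ``n = (2*(B8A^2 - B4^2) + 1.5*B8A + 0.5*B4) / (B8A + B4 + 0.5)``
  and ``GEMI = n*(1 - 0.25*n) - (B4 - 0.125)/(1 - B4)``.
* In PVI/WDVI/TSAVI the coefficient multiplying the red band is the
  soil-line slope ``s`` and the additive constant is the intercept ``a``.
* GNDVI is computed from B7 and B3.

Pixels where any required denominator falls within ``DENOM_TOL`` of zero
are masked rather than propagated as infinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UnknownIndexError
from .grids import Grid, ReflectanceStack

#: Absolute tolerance below which a denominator is treated as zero.
DENOM_TOL = 1e-9

INDEX_NAMES = (
    "ARVI", "DVI", "EVI", "GEMI", "GNDVI", "MSAVI", "NDI45", "NDVI",
    "PVI", "RVI", "REIP", "SAVI", "TNDVI", "TSAVI", "WDVI",
)

#: Bands each index reads, used for validation and error messages.
REQUIRED_BANDS = {
    "ARVI": ("B2", "B4", "B8"),
    "DVI": ("B4", "B8"),
    "EVI": ("B2", "B4", "B8"),
    "GEMI": ("B4", "B8A"),
    "GNDVI": ("B3", "B7"),
    "MSAVI": ("B4", "B8"),
    "NDI45": ("B4", "B5"),
    "NDVI": ("B4", "B8"),
    "PVI": ("B4", "B8"),
    "RVI": ("B4", "B8"),
    "REIP": ("B4", "B5", "B6", "B7"),
    "SAVI": ("B4", "B8"),
    "TNDVI": ("B4", "B8"),
    "TSAVI": ("B4", "B8"),
    "WDVI": ("B4", "B8"),
}


@dataclass(frozen=True)
class IndexParams:
    """Soil-line and calibration constants for the soil-adjusted indices.

    Defaults are standard published values: soil-line intercept a = 0.08,
    slope s = 1.2, soil-noise factor X = 0.08, SAVI L = 0.5.
    """

    soil_intercept_a: float = 0.08
    soil_slope_s: float = 1.2
    soil_noise_X: float = 0.08
    savi_L: float = 0.5

    def __post_init__(self) -> None:
        if self.soil_slope_s <= 0:
            raise ValueError("soil-line slope must be > 0")
        if self.savi_L < 0:
            raise ValueError("SAVI L must be >= 0")


@dataclass
class IndexCube:
    """The 15 index layers derived from one reflectance stack."""

    layers: dict[str, Grid]
    month: int = 1

    def __post_init__(self) -> None:
        missing = set(INDEX_NAMES) - set(self.layers)
        if missing:
            raise UnknownIndexError(f"cube is missing layers: {sorted(missing)}")

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def to_matrix(self, names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack layers into an (n_valid_pixels, n_indices) matrix.

        Returns ``(matrix, valid_mask)`` where ``valid_mask`` is the 2-D
        boolean grid of pixels valid in *every* requested layer.
        """
        names = list(names) if names is not None else list(INDEX_NAMES)
        valid = np.ones(self.layers[names[0]].shape, dtype=bool)
        for n in names:
            valid &= self.layers[n].valid
        mat = np.column_stack([self.layers[n].values[valid] for n in names])
        return mat, valid


def _safe_div(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise division returning (values, invalid_mask)."""
    bad = np.abs(den) < DENOM_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out, bad


def _eval_index(name: str, b: dict[str, np.ndarray], p: IndexParams):
    """Evaluate one index formula; returns (values, invalid_mask)."""
    zeros = np.zeros_like(next(iter(b.values())), dtype=bool)
    if name == "NDVI":
        return _safe_div(b["B8"] - b["B4"], b["B8"] + b["B4"])
    if name == "DVI":
        return b["B8"] - b["B4"], zeros
    if name == "RVI":
        return _safe_div(b["B8"], b["B4"])
    if name == "EVI":
        return _safe_div(2.5 * (b["B8"] - b["B4"]),
                         b["B8"] + 6.0 * b["B4"] - 7.5 * b["B2"] + 1.0)
    if name == "ARVI":
        rb = 2.0 * b["B4"] - b["B2"]
        return _safe_div(b["B8"] - rb, b["B8"] + rb)
    if name == "GNDVI":
        return _safe_div(b["B7"] - b["B3"], b["B7"] + b["B3"])
    if name == "NDI45":
        return _safe_div(b["B5"] - b["B4"], b["B5"] + b["B4"])
    if name == "MSAVI":
        t = 2.0 * b["B8"] + 1.0
        rad = t * t - 8.0 * (b["B8"] - b["B4"])
        bad = rad < 0
        return (t - np.sqrt(np.where(bad, 0.0, rad))) / 2.0, bad
    if name == "GEMI":
        n_num = 2.0 * (b["B8A"] ** 2 - b["B4"] ** 2) + 1.5 * b["B8A"] + 0.5 * b["B4"]
        n, bad1 = _safe_div(n_num, b["B8A"] + b["B4"] + 0.5)
        corr, bad2 = _safe_div(b["B4"] - 0.125, 1.0 - b["B4"])
        return n * (1.0 - 0.25 * n) - corr, bad1 | bad2
    if name == "REIP":
        ratio, bad = _safe_div((b["B4"] + b["B7"]) / 2.0 - b["B5"], b["B6"] - b["B5"])
        return 705.0 + 35.0 * ratio, bad
    if name == "SAVI":
        L = p.savi_L
        v, bad = _safe_div(b["B8"] - b["B4"], b["B8"] + b["B4"] + L)
        return (1.0 + L) * v, bad
    if name == "TNDVI":
        ndvi, bad = _safe_div(b["B8"] - b["B4"], b["B8"] + b["B4"])
        rad = ndvi + 0.5
        neg = rad < 0
        return np.sqrt(np.where(neg | bad, 0.0, rad)), bad | neg
    if name == "PVI":
        s, a = p.soil_slope_s, p.soil_intercept_a
        return (b["B8"] - s * b["B4"] - a) / np.sqrt(s * s + 1.0), zeros
    if name == "WDVI":
        return b["B8"] - p.soil_slope_s * b["B4"], zeros
    if name == "TSAVI":
        s, a, X = p.soil_slope_s, p.soil_intercept_a, p.soil_noise_X
        num = s * (b["B8"] - s * b["B4"] - a)
        den = a * b["B8"] + b["B4"] - a * s + X * (1.0 + s * s)
        return _safe_div(num, den)
    raise UnknownIndexError(
        f"unknown index {name!r}; expected one of {', '.join(INDEX_NAMES)}"
    )


def compute_index(stack: ReflectanceStack, name: str,
                  params: IndexParams | None = None) -> Grid:
    """Compute one named vegetation index over a reflectance stack.

    Pixels where a denominator (or radicand) is degenerate are masked.
    Emits a warning (not an error) if every output pixel ends up masked.
    """
    if name not in INDEX_NAMES:
        raise UnknownIndexError(
            f"unknown index {name!r}; expected one of {', '.join(INDEX_NAMES)}"
        )
    params = params or IndexParams()
    bands = {bn: stack.band(bn) for bn in REQUIRED_BANDS[name]}
    values, bad = _eval_index(name, bands, params)
    out = Grid(np.where(bad, np.nan, values), stack.mask | bad,
               stack.transform, stack.crs)
    if out.mask.all():
        warnings.warn(f"all pixels masked in index {name}", stacklevel=2)
    return out


def compute_all(stack: ReflectanceStack, params: IndexParams | None = None) -> IndexCube:
    """Compute all 15 index layers for one stack; masks are propagated."""
    params = params or IndexParams()
    layers = {name: compute_index(stack, name, params) for name in INDEX_NAMES}
    return IndexCube(layers=layers, month=stack.month)
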