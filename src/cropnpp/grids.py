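"""Georeferenced grid containers shared by every stage of the pipeline.

A :class:`Grid` is a 2-D float field plus a validity mask and a lightweight
georeference (affine transform as a 6-tuple ``(a, b, c, d, e, f)`` mapping
``col, row -> x = a*col + b*row + c, y = d*col + e*row + f``, and a CRS
identifier string). A :class:`ReflectanceStack` bundles the multispectral
bands of one acquisition.

The mask convention follows numpy.ma: ``mask == True`` marks an *invalid*
pixel. Masked pixels are excluded from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import MissingBandError, ShapeMismatchError

#: Sentinel-2 band names the pipeline knows about, in wavelength order.
BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A")

#: Identity transform used when no georeference is supplied (unit pixels).
IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)

# Reflectance sanity window: slightly negative values are sensor noise and
# get clamped to zero; values beyond 1.2 are physically implausible.
REFLECTANCE_CLAMP_LO = -0.01
REFLECTANCE_MAX = 1.2


@dataclass
class Grid:
    """A single 2-D field with validity mask and georeference."""

    values: np.ndarray
    mask: np.ndarray | None = None
    transform: tuple = IDENTITY_TRANSFORM
    crs: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ShapeMismatchError(
                    f"mask shape {self.mask.shape} != values shape {self.values.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid of valid (unmasked) pixels."""
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        """1-D array of values at valid pixels."""
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray, extra_mask: np.ndarray | None = None) -> "Grid":
        """New grid sharing this georeference; mask is the union of masks."""
        mask = self.mask.copy()
        if extra_mask is not None:
            mask |= np.asarray(extra_mask, dtype=bool)
        return Grid(np.asarray(values, float), mask, self.transform, self.crs)

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.mask.copy(), self.transform, self.crs)


def check_aligned(*grids: Grid) -> None:
    """Raise ShapeMismatchError unless all grids share shape, transform and CRS."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ShapeMismatchError(f"grid shapes differ: {g.shape} vs {ref.shape}")
        if not np.allclose(g.transform, ref.transform):
            raise ShapeMismatchError("grid transforms differ")
        if g.crs != ref.crs:
            raise ShapeMismatchError(f"CRS mismatch: {g.crs!r} vs {ref.crs!r}")


@dataclass
class ReflectanceStack:
    """Multiband surface reflectance for one acquisition.

    Bands are dimensionless surface reflectance, nominally in [0, 1.2].
    Values in (-0.01, 0) are clamped to 0 at validation; values outside
    [-0.01, 1.2] are masked as invalid.
    """

    bands: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    transform: tuple = IDENTITY_TRANSFORM
    crs: str = "local"
    month: int = 1

    def __post_init__(self) -> None:
        if not self.bands:
            raise MissingBandError("stack has no bands")
        shapes = {np.asarray(v).shape for v in self.bands.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"band grids have differing shapes: {shapes}")
        shape = shapes.pop()
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ShapeMismatchError("mask shape differs from band shape")
        clean = {}
        for name, arr in self.bands.items():
            arr = np.asarray(arr, dtype=float).copy()
            bad = ~np.isfinite(arr) | (arr < REFLECTANCE_CLAMP_LO) | (arr > REFLECTANCE_MAX)
            near_zero = (arr > REFLECTANCE_CLAMP_LO) & (arr < 0)
            arr[near_zero] = 0.0
            self.mask = self.mask | bad
            clean[name] = arr
        self.bands = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise MissingBandError(
                f"band {name!r} not present (have: {sorted(self.bands)})"
            ) from None

    def band_grid(self, name: str) -> Grid:
        return Grid(self.band(name), self.mask.copy(), self.transform, self.crs)

    def grid_template(self) -> Grid:
        """An empty grid carrying this stack's georeference and mask."""
        return Grid(np.zeros(self.shape), self.mask.copy(), self.transform, self.crs)
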