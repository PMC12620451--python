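"""Raster and table I/O.

Rasters are multiband TIFF files written with ``tifffile``; the affine
transform, CRS identifier, band names, acquisition month and nodata
convention travel in a JSON document stored in the TIFF
ImageDescription tag. Masked pixels are written as NaN. Write-then-read
round-trips values, mask and georeference exactly.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from .errors import ShapeMismatchError
from .grids import Grid, ReflectanceStack

_FORMAT = "cropnpp-raster-v1"


def _meta(transform, crs, band_names, month=None) -> str:
    return json.dumps({"format": _FORMAT, "transform": list(transform),
                       "crs": crs, "band_names": list(band_names),
                       "month": month, "nodata": "nan"})


def write_raster(data: Grid | ReflectanceStack | dict[str, Grid], path) -> None:
    """Write a grid, a reflectance stack, or named grids to multiband TIFF."""
    if isinstance(data, Grid):
        layers, names = [data], ["layer"]
        transform, crs, month = data.transform, data.crs, None
    elif isinstance(data, ReflectanceStack):
        names = list(data.bands)
        layers = [Grid(data.bands[n], data.mask, data.transform, data.crs)
                  for n in names]
        transform, crs, month = data.transform, data.crs, data.month
    else:
        names = list(data)
        layers = [data[n] for n in names]
        transform, crs, month = layers[0].transform, layers[0].crs, None
    arr = np.stack([np.where(g.mask, np.nan, g.values) for g in layers])
    tifffile.imwrite(path, arr.astype(np.float64), photometric="minisblack",
                     description=_meta(transform, crs, names, month))


def _read(path):
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    if meta.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a cropnpp raster")
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float), meta


def read_raster(path) -> dict[str, Grid]:
    """Read a multiband raster back as named grids (NaN pixels masked)."""
    arr, meta = _read(path)
    transform = tuple(meta["transform"])
    out = {}
    for i, name in enumerate(meta["band_names"]):
        vals = arr[i]
        out[name] = Grid(vals, ~np.isfinite(vals), transform, meta["crs"])
    return out


def read_grid(path) -> Grid:
    """Read a single-band raster as one grid."""
    grids = read_raster(path)
    if len(grids) != 1:
        raise ValueError(f"{path}: expected a single band, found {len(grids)}")
    return next(iter(grids.values()))


def read_stack(path, expected_crs: str | None = None) -> ReflectanceStack:
    """Read a multiband raster as a reflectance stack."""
    arr, meta = _read(path)
    if expected_crs is not None and meta["crs"] != expected_crs:
        raise ShapeMismatchError(
            f"{path}: CRS {meta['crs']!r} does not match expected {expected_crs!r}")
    mask = ~np.all(np.isfinite(arr), axis=0)
    bands = {n: np.nan_to_num(arr[i], nan=0.0)
             for i, n in enumerate(meta["band_names"])}
    return ReflectanceStack(bands=bands, mask=mask,
                            transform=tuple(meta["transform"]), crs=meta["crs"],
                            month=meta.get("month") or 1)


def write_samples_csv(path, sample_ids, lon, lat, month, matrix, names,
                      fpar=None) -> None:
    """Export per-sample index values (and optional FPAR labels) to CSV."""
    df = pd.DataFrame(matrix, columns=list(names))
    df.insert(0, "month", month)
    df.insert(0, "lat", lat)
    df.insert(0, "lon", lon)
    df.insert(0, "sample_id", sample_ids)
    if fpar is not None:
        df["fpar"] = fpar
    df.to_csv(path, index=False)


def read_samples_csv(path):
    """Read a training CSV; returns (FeatureMatrix, fpar_or_None)."""
    from .fpar import FeatureMatrix
    from .indices import INDEX_NAMES

    df = pd.read_csv(path)
    names = [n for n in INDEX_NAMES if n in df.columns]
    if not names:
        raise ValueError(f"{path}: no vegetation-index columns found")
    fpar = df["fpar"].to_numpy(float) if "fpar" in df.columns else None
    return FeatureMatrix(df[names].to_numpy(float), names), fpar
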