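"""Spectral indices (NDVI, NDMI, BSI) and polygon zonal statistics.

Indices are computed elementwise on the 10 m composite. Healthy vegetation
reflects strongly in the near-infrared and absorbs red light, so NDVI rises
with canopy health; NDMI contrasts near-infrared against shortwave infrared
and tracks moisture; BSI contrasts (SWIR + red) against (NIR + blue) and
rises where bare soil shows. All three are normalized differences in
[-1, 1]; a vanishing denominator yields nodata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .compositing import Composite
from .grids import GeoTransform

INDEX_NAMES = ("ndvi", "ndmi", "bsi")


@dataclass
class IndexGrid:
    index_name: str
    values: np.ndarray
    transform: GeoTransform
    year: int | None = None
    tile_id: str | None = None


def _normalized_difference(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _require_bands(composite: Composite, names: tuple[str, ...]) -> list[np.ndarray]:
    grids = []
    for n in names:
        if n not in composite.bands:
            raise ValueError(f"composite is missing band {n}")
        grids.append(np.asarray(composite.bands[n], dtype=float))
    return grids


def compute_ndvi(composite: Composite) -> IndexGrid:
    """NDVI = (B08 - B04) / (B08 + B04)."""
    b04, b08 = _require_bands(composite, ("B04", "B08"))
    return _make(composite, "ndvi", _normalized_difference(b08 - b04, b08 + b04))


def compute_ndmi(composite: Composite) -> IndexGrid:
    """NDMI = (B08 - B11) / (B08 + B11)."""
    b08, b11 = _require_bands(composite, ("B08", "B11"))
    return _make(composite, "ndmi", _normalized_difference(b08 - b11, b08 + b11))


def compute_bsi(composite: Composite) -> IndexGrid:
    """BSI = ((B11 + B04) - (B08 + B02)) / ((B11 + B04) + (B08 + B02))."""
    b02, b04, b08, b11 = _require_bands(composite, ("B02", "B04", "B08", "B11"))
    num = (b11 + b04) - (b08 + b02)
    den = (b11 + b04) + (b08 + b02)
    return _make(composite, "bsi", _normalized_difference(num, den))


def compute_index(composite: Composite, name: str) -> IndexGrid:
    try:
        fn = {"ndvi": compute_ndvi, "ndmi": compute_ndmi, "bsi": compute_bsi}[name]
    except KeyError:
        raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    return fn(composite)


def _make(composite: Composite, name: str, values: np.ndarray) -> IndexGrid:
    values = np.where(composite.valid_mask, values, np.nan)
    return IndexGrid(
        index_name=name,
        values=values,
        transform=composite.transform,
        year=composite.year,
        tile_id=composite.tile_id,
    )


def annual_index_means(index_table, weighting: str = "plantation"):
    """Pooled per-year index means across plantations.

    ``index_table`` holds one row per plantation-year with columns ``year``,
    the index columns, and (for pixel weighting) ``pixel_count``. Plantation
    weighting (the default) averages the per-plantation means; pixel
    weighting weights each plantation by its contributing pixel count.
    """
    import pandas as pd

    cols = [c for c in INDEX_NAMES if c in index_table.columns]
    if weighting == "plantation":
        return index_table.groupby("year")[cols].mean()
    if weighting == "pixel":
        if "pixel_count" not in index_table.columns:
            raise ValueError("pixel weighting needs a pixel_count column")

        def _wmean(g):
            w = g["pixel_count"].to_numpy(dtype=float)
            return pd.Series({c: np.average(g[c], weights=w) for c in cols})

        return index_table.groupby("year").apply(_wmean, include_groups=False)
    raise ValueError(f"unknown weighting {weighting!r}")


def pixels_in_polygon(
    shape: tuple[int, int], transform: GeoTransform, polygon
) -> np.ndarray:
    """Boolean grid: True where the pixel center falls inside the polygon."""
    x, y = transform.pixel_centers(shape)
    xx, yy = np.meshgrid(x, y)
    return shapely.contains_xy(polygon, xx, yy)


def zonal_mean(index: IndexGrid, polygon) -> tuple[float, int]:
    """Unweighted mean of index values at pixel centers inside the polygon.

    Nodata pixels are excluded. Returns (mean, count of contributing pixels);
    raises if the polygon covers no pixel center or only nodata pixels.
    """
    inside = pixels_in_polygon(index.values.shape, index.transform, polygon)
    if not inside.any():
        raise ValueError("polygon covers no pixel center of the grid")
    vals = index.values[inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("zero valid pixels inside polygon")
    return float(vals.mean()), int(vals.size)
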