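"""Raster grid primitives: geotransform, nodata handling, TIFF and GeoJSON I/O.

All grids are row-major numpy arrays in a north-up, pixel-center-registered
frame. Nodata is carried as NaN in float grids; any arithmetic touching
nodata therefore yields nodata without special casing. Rasters are stored as
plain (multi-band) TIFF with a JSON sidecar holding the spatial metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

#: Sentinel-2 band names in canonical order.
BAND_NAMES = (
    "B01", "B02", "B03", "B04", "B05", "B06", "B07",
    "B08", "B8A", "B09", "B10", "B11", "B12",
)

#: Native ground-sample distance per band, metres.
BAND_RESOLUTION = {
    "B01": 60, "B02": 10, "B03": 10, "B04": 10, "B05": 20, "B06": 20,
    "B07": 20, "B08": 10, "B8A": 20, "B09": 60, "B10": 60, "B11": 20,
    "B12": 20,
}

NODATA = np.nan


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine geotransform.

    ``x0, y0`` are the coordinates of the *outer corner* of the top-left
    pixel; ``pixel_size`` is the square pixel edge in metres. Pixel centers
    sit at ``x0 + (col + 0.5) * pixel_size`` / ``y0 - (row + 0.5) * pixel_size``.
    """

    x0: float
    y0: float
    pixel_size: float

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center-coordinate vectors for a grid of ``shape``."""
        rows, cols = shape
        x = self.x0 + (np.arange(cols) + 0.5) * self.pixel_size
        y = self.y0 - (np.arange(rows) + 0.5) * self.pixel_size
        return x, y

    def at_resolution(self, pixel_size: float) -> "GeoTransform":
        return GeoTransform(self.x0, self.y0, pixel_size)

    def to_json(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "pixel_size": self.pixel_size}

    @classmethod
    def from_json(cls, d: dict) -> "GeoTransform":
        return cls(float(d["x0"]), float(d["y0"]), float(d["pixel_size"]))


def is_nodata(grid: np.ndarray) -> np.ndarray:
    return np.isnan(grid)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(
    path: str | Path,
    bands: dict[str, np.ndarray] | np.ndarray,
    transform: GeoTransform,
    *,
    metadata: dict | None = None,
) -> None:
    """Write a single- or multi-band raster as TIFF plus a JSON sidecar.

    ``bands`` may be a dict band-name -> 2D grid (all same shape) or a bare
    2D array for single-band rasters.
    """
    path = Path(path)
    if isinstance(bands, dict):
        names = list(bands)
        stack = np.stack([np.asarray(bands[n]) for n in names])
    else:
        names = ["band_1"]
        stack = np.asarray(bands)[None, ...]
    tifffile.imwrite(path, stack)
    meta = {"bands": names, "geotransform": transform.to_json()}
    if metadata:
        meta.update(metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_raster(path: str | Path) -> tuple[dict[str, np.ndarray], GeoTransform, dict]:
    """Read a raster written by :func:`write_raster`.

    Returns (bands dict, geotransform, full sidecar metadata).
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    meta = json.loads(_sidecar(path).read_text())
    names = meta["bands"]
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"{path}: sidecar lists {len(names)} bands, file has {stack.shape[0]}"
        )
    bands = {n: stack[i] for i, n in enumerate(names)}
    return bands, GeoTransform.from_json(meta["geotransform"]), meta


def read_geojson_features(path: str | Path) -> Iterator[tuple[object, dict]]:
    """Yield (shapely geometry, properties) from a GeoJSON FeatureCollection."""
    from shapely.geometry import shape

    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    for feat in doc["features"]:
        yield shape(feat["geometry"]), dict(feat.get("properties") or {})


def write_geojson_features(
    path: str | Path, features: list[tuple[object, dict]]
) -> None:
    from shapely.geometry import mapping

    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(doc))
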