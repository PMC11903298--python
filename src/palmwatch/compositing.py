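"""Annual cloud-free composites from repeated multispectral tile captures.

A tile is observed several times within a short window; each capture comes
with a provider cloud mask that is known to miss some cloud. Residual cloud
is screened by comparing each capture pixel-by-pixel against the
cross-capture consensus (median) in the bright visible bands and flagging
large positive deviations ("delta" screening). Surviving observations are
merged per pixel with a median, after every band has been up-sampled to a
common 10 m grid with a linear (bilinear) kernel.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import BAND_NAMES, BAND_RESOLUTION, GeoTransform

#: Bands used for the cross-capture deviation test. Clouds are bright in the
#: visible, so blue and red give the cleanest contrast against vegetation.
DELTA_REFERENCE_BANDS = ("B02", "B04")

#: Default deviation threshold (reflectance units) above which a capture's
#: pixel is declared residual cloud.
DEFAULT_TAU = 0.12

#: Default maximum date span (days) within which captures are assumed to view
#: an unchanged surface.
DEFAULT_WINDOW_DAYS = 15


@dataclass
class TileCapture:
    """One dated multispectral acquisition of a tile.

    ``bands`` maps band name to a 2D reflectance grid at that band's native
    resolution; ``cloud_mask`` is a boolean grid at 10 m (True = cloudy).
    """

    tile_id: str
    date: _dt.date
    bands: dict[str, np.ndarray]
    transform: GeoTransform
    cloud_mask: np.ndarray = None
    crs: str = "EPSG:32650"

    def __post_init__(self):
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise ValueError(f"capture {self.tile_id}/{self.date}: missing bands {missing}")
        shape10 = self.bands["B02"].shape
        for name, grid in self.bands.items():
            ratio = BAND_RESOLUTION[name] // 10
            expect = (shape10[0] // ratio, shape10[1] // ratio)
            if grid.shape != expect and grid.shape != shape10:
                raise ValueError(
                    f"band {name}: shape {grid.shape} matches neither native "
                    f"{expect} nor 10 m {shape10}"
                )
        if self.cloud_mask is None:
            self.cloud_mask = np.zeros(shape10, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["B02"].shape


@dataclass
class Composite:
    """Cloud-free annual composite: all 13 bands at 10 m on one grid."""

    tile_id: str
    year: int
    bands: dict[str, np.ndarray]
    transform: GeoTransform
    valid_mask: np.ndarray
    provenance: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid_mask.shape


def upsample_band(grid: np.ndarray, ratio: int) -> np.ndarray:
    """Up-sample a 20 m or 60 m band to 10 m with a linear kernel.

    Pixel-center registration: target center ``i`` maps to source coordinate
    ``(i + 0.5) / ratio - 0.5``; edges are clamped. Nodata (NaN) contaminates
    every target pixel whose 2x2 interpolation stencil touches it.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if ratio < 1 or int(ratio) != ratio:
        raise ValueError(f"resolution ratio must be a positive integer, got {ratio}")
    if ratio == 1:
        return grid.copy()
    rows, cols = grid.shape
    r = (np.arange(rows * ratio) + 0.5) / ratio - 0.5
    c = (np.arange(cols * ratio) + 0.5) / ratio - 0.5
    rr, cc = np.meshgrid(r, c, indexing="ij")
    # order=1 bilinear; NaN propagates through any touched stencil cell
    return map_coordinates(grid, [rr, cc], order=1, mode="nearest")


def upsample_capture(capture: TileCapture) -> dict[str, np.ndarray]:
    """Return all bands of a capture on the 10 m grid."""
    shape10 = capture.shape
    out = {}
    for name in BAND_NAMES:
        grid = capture.bands[name]
        if grid.shape == shape10:
            out[name] = np.asarray(grid, dtype=float)
        else:
            out[name] = upsample_band(grid, shape10[0] // grid.shape[0])
    return out


def delta_cloud_filter(
    captures: list[TileCapture],
    *,
    tau: float = DEFAULT_TAU,
    window_days: int = DEFAULT_WINDOW_DAYS,
    reference_bands: tuple[str, ...] = DELTA_REFERENCE_BANDS,
) -> list[np.ndarray]:
    """Flag residual cloud by pixel-wise comparison across >=3 near-simultaneous captures.

    For each capture and pixel, the deviation of the capture's reflectance
    from the per-pixel cross-capture consensus is computed in the reference
    bands; the pixel is flagged cloudy for that capture when it exceeds the
    consensus by more than ``tau`` in any reference band. The consensus is
    the median over captures not already flagged by their provided cloud
    masks, and only positive deviations flag: clouds brighten the visible
    bands, and a one-sided rule keeps a clean capture from being discarded
    when the other captures at a pixel are cloudy. Returns one boolean mask
    per capture, to be unioned with the provided cloud masks downstream.
    """
    if len(captures) < 3:
        raise ValueError(f"delta filter needs >=3 captures, got {len(captures)}")
    dates = [c.date for c in captures]
    span = (max(dates) - min(dates)).days
    if span > window_days:
        raise ValueError(
            f"capture dates span {span} days, exceeding the {window_days}-day window"
        )
    provided = np.stack([c.cloud_mask for c in captures])
    flags = [np.zeros(c.shape, dtype=bool) for c in captures]
    for band in reference_bands:
        stack = np.stack([upsample_capture_band(c, band) for c in captures])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-masked pixels
            consensus = np.nanmedian(np.where(provided, np.nan, stack), axis=0)
        dev = stack - consensus
        exceed = dev > tau  # NaN comparisons are False: nodata never flags
        for i in range(len(captures)):
            flags[i] |= exceed[i]
    return flags


def upsample_capture_band(capture: TileCapture, band: str) -> np.ndarray:
    grid = capture.bands[band]
    if grid.shape == capture.shape:
        return np.asarray(grid, dtype=float)
    return upsample_band(grid, capture.shape[0] // grid.shape[0])


def build_composite(
    captures: list[TileCapture],
    *,
    year: int | None = None,
    tau: float = DEFAULT_TAU,
    window_days: int = DEFAULT_WINDOW_DAYS,
    apply_delta: bool = True,
    mask_dilation: int = 2,
) -> Composite:
    """Merge captures into a cloud-free composite.

    Per pixel and band, the composite value is the median over captures whose
    pixel is flagged neither by the provided cloud mask nor by the delta
    screen. Each capture's combined cloud mask is dilated by
    ``mask_dilation`` pixels before merging — standard practice that
    suppresses semi-transparent cloud edges and isolated unflagged pixels
    inside cloud patches. ``provenance`` counts contributing captures;
    pixels never seen cloud-free are nodata in every band.
    """
    if not captures:
        raise ValueError("no captures")
    t0 = captures[0].transform
    shape = captures[0].shape
    for c in captures[1:]:
        if c.transform != t0 or c.shape != shape:
            raise ValueError("captures have inconsistent geotransforms or shapes")
    if apply_delta and len(captures) >= 3:
        delta = delta_cloud_filter(captures, tau=tau, window_days=window_days)
    else:
        delta = [np.zeros(shape, dtype=bool) for _ in captures]
    cloudy = np.stack([c.cloud_mask | d for c, d in zip(captures, delta)])
    if mask_dilation > 0:
        from scipy.ndimage import binary_dilation

        struct = np.ones((3, 3), dtype=bool)
        cloudy = np.stack(
            [binary_dilation(m, structure=struct, iterations=mask_dilation) for m in cloudy]
        )
    provenance = np.sum(~cloudy, axis=0).astype(np.int32)
    valid = provenance > 0

    bands = {}
    for name in BAND_NAMES:
        stack = np.stack([upsample_capture_band(c, name) for c in captures])
        stack = np.where(cloudy, np.nan, stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            merged = np.nanmedian(stack, axis=0)
        merged[~valid] = np.nan
        bands[name] = merged

    return Composite(
        tile_id=captures[0].tile_id,
        year=year if year is not None else captures[0].date.year,
        bands=bands,
        transform=t0.at_resolution(10.0),
        valid_mask=valid,
        provenance=provenance,
        metadata={
            "dates": [c.date.isoformat() for c in captures],
            "tau": tau,
            "n_captures": len(captures),
        },
    )
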