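import datetime as dt

import numpy as np
import pytest

from palmwatch.compositing import Composite, TileCapture
from palmwatch.grids import BAND_NAMES, BAND_RESOLUTION, GeoTransform

TRANSFORM = GeoTransform(600000.0, 620000.0, 10.0)


def make_capture(
    shape10=(12, 12),
    value=0.3,
    date=dt.date(2020, 6, 1),
    cloud_mask=None,
    band_values=None,
    native=True,
):
    """A small capture with constant bands (optionally per-band values).

    With ``native=True`` the 20/60 m bands are created at their native
    coarse resolution; otherwise everything is at 10 m.
    """
    bands = {}
    for name in BAND_NAMES:
        v = value if band_values is None else band_values.get(name, value)
        if native:
            ratio = BAND_RESOLUTION[name] // 10
            sh = (shape10[0] // ratio, shape10[1] // ratio)
        else:
            sh = shape10
        bands[name] = np.full(sh, v, dtype=float)
    return TileCapture(
        tile_id="50NNM", date=date, bands=bands, transform=TRANSFORM, cloud_mask=cloud_mask
    )


def make_composite(band_values, shape=(4, 4), valid=None):
    """A composite with constant per-band values on a small 10 m grid."""
    bands = {}
    for name in BAND_NAMES:
        v = band_values.get(name, 0.2)
        bands[name] = np.full(shape, float(v)) if np.isscalar(v) else np.asarray(v, dtype=float)
    if valid is None:
        valid = ~np.isnan(bands["B02"])
    return Composite(
        tile_id="50NNM",
        year=2018,
        bands=bands,
        transform=TRANSFORM,
        valid_mask=valid,
        provenance=valid.astype(np.int32),
    )


@pytest.fixture
def transform():
    return TRANSFORM
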