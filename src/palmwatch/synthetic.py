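"""Synthetic multispectral scenes and plantation-year panels with known truth.

The scene generator emulates the observational setting of a plantation
survey: a tropical tile observed several times within a few days, with the
same land surface under independent sensor noise and independently drifting
cumulus-like cloud fields. Each capture carries a deliberately imperfect
cloud mask (a fraction of cloudy pixels is left unflagged) so that the
cross-capture delta screen has residual cloud to catch. Ground-truth
land-cover class grids and panel regression coefficients are returned
alongside, making every downstream stage testable without any download.

Class spectra are configuration, not ground truth: the defaults are chosen
within published typical reflectance ranges for dense palm canopy, young
stands, mixed vegetation, bare soil and water, and calibrated so that the
index levels of a palm-dominated scene fall where field observations of
producing plantations put them (NDVI ~ 0.7, strongly negative BSI, high
NDMI).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .compositing import TileCapture
from .grids import BAND_NAMES, GeoTransform

#: Ground-truth class codes used in scene class maps.
TRUTH_CLASSES = (
    "oil_palm_mature", "oil_palm_immature", "other_vegetation", "bare_soil", "water",
)
TRUTH_CODES = {name: i for i, name in enumerate(TRUTH_CLASSES)}

#: Ground-truth class -> land-cover class of the classification stage.
TRUTH_TO_LANDCOVER = {
    0: "oil_palm_mature",
    1: "oil_palm_immature",
    2: "other_vegetation",
    3: "other",
    4: "other",
}

#: Mean reflectance per band (B01..B12, B8A in canonical order) per class.
#: Values sit in published typical ranges; SWIR levels are set low for palm
#: canopy so scene-level NDMI/BSI land near observed plantation values.
DEFAULT_SPECTRA = {
    "oil_palm_mature":   [0.035, 0.030, 0.060, 0.040, 0.090, 0.220, 0.300, 0.340, 0.360, 0.120, 0.005, 0.015, 0.008],
    "oil_palm_immature": [0.050, 0.050, 0.080, 0.090, 0.130, 0.200, 0.250, 0.280, 0.290, 0.110, 0.005, 0.060, 0.030],
    "other_vegetation":  [0.040, 0.040, 0.070, 0.050, 0.100, 0.160, 0.220, 0.260, 0.270, 0.110, 0.005, 0.030, 0.015],
    "bare_soil":         [0.130, 0.120, 0.160, 0.220, 0.250, 0.270, 0.280, 0.300, 0.310, 0.200, 0.010, 0.420, 0.350],
    "water":             [0.050, 0.040, 0.030, 0.020, 0.015, 0.012, 0.010, 0.008, 0.007, 0.004, 0.002, 0.004, 0.003],
}

#: Bright, spectrally flat cumulus spectrum used to overwrite cloudy pixels.
CLOUD_SPECTRUM = [0.78, 0.76, 0.75, 0.74, 0.73, 0.72, 0.71, 0.70, 0.70, 0.65, 0.30, 0.45, 0.40]

#: Land-cover composition of the default palm-dominated scene.
DEFAULT_CLASS_SHARES = {
    "oil_palm_mature": 0.55,
    "oil_palm_immature": 0.10,
    "other_vegetation": 0.15,
    "bare_soil": 0.12,
    "water": 0.08,
}

#: Annual Malaysian palm-oil trade price, MYR per metric ton (Dec 31 exchange
#: date). 2018 (study-period minimum) and 2021 (maximum) are the observed
#: anchors; the remaining years are synthetic in-between values.
DEFAULT_PRICES = {
    2017: 2560.0, 2018: 1940.0, 2019: 2280.0, 2020: 3520.0,
    2021: 5046.0, 2022: 4190.0, 2023: 3700.0,
}

PLANTATION_TYPES = ("own_estate", "outside_supplier_estate", "small_grower")

#: Plantation-type composition, matching a survey where roughly a fifth of
#: plantations are own estates and half are small-grower managed.
DEFAULT_TYPE_SHARES = (28 / 144, 39 / 144, 77 / 144)


@dataclass
class SceneSpec:
    """Parameters of one synthetic tile scene."""

    width: int = 120
    height: int = 120
    pixel_size: float = 10.0
    class_map: np.ndarray | None = None          # int codes per TRUTH_CODES
    class_shares: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SHARES))
    class_spectra: dict[str, list[float]] = field(default_factory=lambda: dict(DEFAULT_SPECTRA))
    noise_sd: float = 0.015
    cloud_fraction: float = 0.2
    mask_miss_rate: float = 0.10    # fraction of cloud pixels absent from the provided mask
    n_captures: int = 3
    tile_id: str = "50NNM"
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError(f"cloud_fraction must be in [0, 1], got {self.cloud_fraction}")
        if not 0.0 <= self.mask_miss_rate <= 1.0:
            raise ValueError("mask_miss_rate must be in [0, 1]")
        if self.n_captures < 3:
            raise ValueError("need at least 3 captures for the delta screen")
        for cname, spec in self.class_spectra.items():
            if len(spec) != len(BAND_NAMES):
                raise ValueError(f"class {cname}: spectrum must cover all {len(BAND_NAMES)} bands")


@dataclass
class PanelSpec:
    """Parameters of one synthetic plantation-year panel."""

    n_plantations: int = 96
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021, 2022, 2023)
    reference_year: int = 2018
    true_betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    random_intercept_sd: float = 0.10
    residual_sd: float = 0.05
    type_shares: tuple[float, float, float] = DEFAULT_TYPE_SHARES
    share_certified_2018: float = 1 / 3
    prices: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PRICES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_plantations < 2:
            raise ValueError("need at least 2 plantations")
        if len(self.years) < 2:
            raise ValueError("need at least 2 years")
        if abs(sum(self.type_shares) - 1.0) > 1e-9:
            raise ValueError("type_shares must sum to 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        missing = [y for y in self.years if y not in self.prices]
        if missing:
            raise ValueError(f"no price for years {missing}")


#: Default data-generating coefficients for the panel, coverage-fraction
#: units. Year effects are zero (the null); see table2_year_effects() for a
#: decline pattern of the magnitude reported in certification studies.
DEFAULT_TRUE_BETAS = {
    "intercept": -0.35,
    "self_produced": 0.04,
    "outsourced": -0.017,
    "ndvi": 0.75,
    "ndmi": 0.10,
    "bsi": -0.50,
    "price": 0.00002,
}


def table2_year_effects() -> dict[str, float]:
    """A monotone post-reference coverage decline of reported magnitude.

    Year-dummy coefficients on the coverage fraction, 2018 reference,
    running from -0.08 in the first post-reference year to -0.25 in the
    fourth. No effect is placed on the final panel year: its dummy is
    aliased with the annual price (price is constant within a year) and is
    therefore not identifiable in the fitted model.
    """
    return {
        "year_2017": 0.0,
        "year_2019": -0.080,
        "year_2020": -0.120,
        "year_2021": -0.195,
        "year_2022": -0.252,
    }


def _coherent_class_map(height: int, width: int, shares: dict[str, float], rng) -> np.ndarray:
    """Spatially coherent class map with (near-)exact class proportions.

    A smoothed white-noise field is thresholded at the quantiles of the
    cumulative class shares, so patch geometry is blob-like and proportions
    follow the requested shares up to pixel rounding.
    """
    field_ = gaussian_filter(rng.standard_normal((height, width)), sigma=max(2, min(height, width) // 25))
    order = [c for c in TRUTH_CLASSES if shares.get(c, 0) > 0]
    cum = np.cumsum([shares[c] for c in order])
    cum = cum / cum[-1]
    thresholds = np.quantile(field_, cum[:-1]) if len(order) > 1 else []
    out = np.full((height, width), TRUTH_CODES[order[-1]], dtype=np.int16)
    prev = -np.inf
    for cname, thr in zip(order[:-1], thresholds):
        out[(field_ > prev) & (field_ <= thr)] = TRUTH_CODES[cname]
        prev = thr
    return out


def _cloud_field(shape: tuple[int, int], fraction: float, rng) -> np.ndarray:
    """Cloud opacity in [0, 1]: random soft-edged ellipses covering ~fraction."""
    if fraction <= 0:
        return np.zeros(shape)
    h, w = shape
    binary = np.zeros(shape, dtype=bool)
    target = fraction * h * w
    for _ in range(500):
        if binary.sum() >= target:
            break
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(0.04, 0.15) * min(h, w)
        b = rng.uniform(0.04, 0.15) * min(h, w)
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        binary |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    opacity = gaussian_filter(binary.astype(float), sigma=1.2)
    return np.clip(opacity / max(opacity.max(), 1e-9), 0.0, 1.0)


def generate_scene(spec: SceneSpec) -> tuple[list[TileCapture], np.ndarray]:
    """Generate >=3 co-registered captures of one scene plus its ground truth.

    Captures share the land surface (the class map) and differ only in
    per-band sensor noise and in independently placed cloud fields. Cloud
    pixels are blended toward a bright cloud spectrum; each capture's
    provided cloud mask omits a ``mask_miss_rate`` fraction of its truly
    cloudy pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.class_map is not None:
        class_map = np.asarray(spec.class_map, dtype=np.int16)
        if class_map.shape != (spec.height, spec.width):
            raise ValueError("class_map shape does not match scene dimensions")
    else:
        class_map = _coherent_class_map(spec.height, spec.width, spec.class_shares, rng)

    spectra = np.zeros((len(TRUTH_CLASSES), len(BAND_NAMES)))
    for cname, code in TRUTH_CODES.items():
        spectra[code] = spec.class_spectra[cname]
    surface_mean = spectra[class_map]           # (H, W, 13)
    cloud = np.asarray(CLOUD_SPECTRUM)

    transform = GeoTransform(600000.0, 620000.0, spec.pixel_size)
    captures = []
    base_date = _dt.date(2020, 6, 1)
    for i in range(spec.n_captures):
        noise = rng.normal(0.0, spec.noise_sd, surface_mean.shape) if spec.noise_sd > 0 else 0.0
        opacity = _cloud_field((spec.height, spec.width), spec.cloud_fraction, rng)
        truly_cloudy = opacity > 0.05
        refl = surface_mean + noise
        refl = refl * (1 - opacity[..., None]) + cloud[None, None, :] * opacity[..., None]
        refl = np.clip(refl, 0.0, 1.0)
        if spec.mask_miss_rate > 0 and truly_cloudy.any():
            keep = rng.random(truly_cloudy.shape) >= spec.mask_miss_rate
            provided_mask = truly_cloudy & keep
        else:
            provided_mask = truly_cloudy.copy()
        bands = {name: refl[:, :, j].copy() for j, name in enumerate(BAND_NAMES)}
        captures.append(
            TileCapture(
                tile_id=spec.tile_id,
                date=base_date + _dt.timedelta(days=3 * i),
                bands=bands,
                transform=transform,
                cloud_mask=provided_mask,
            )
        )
    return captures, class_map


def clean_surface(spec: SceneSpec, class_map: np.ndarray) -> dict[str, np.ndarray]:
    """Noise- and cloud-free reflectance of a scene: the recovery target."""
    spectra = np.zeros((len(TRUTH_CLASSES), len(BAND_NAMES)))
    for cname, code in TRUTH_CODES.items():
        spectra[code] = spec.class_spectra[cname]
    surface = spectra[np.asarray(class_map, dtype=np.int16)]
    return {name: surface[:, :, j].copy() for j, name in enumerate(BAND_NAMES)}


def generate_plantations(
    n: int,
    scene_shape: tuple[int, int],
    transform: GeoTransform,
    seed: int = 0,
    type_shares: tuple[float, float, float] = DEFAULT_TYPE_SHARES,
) -> list[tuple[object, dict]]:
    """Non-overlapping rectangular plantation polygons tiling the scene.

    Plantations are assigned to six mills; mills 1-3 certify in 2018, mills
    4-6 in 2023, mirroring a producer whose mills certified in two waves.
    Returns (shapely polygon, properties) pairs.
    """
    from shapely.geometry import box

    rng = np.random.default_rng(seed)
    h, w = scene_shape
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    cell_h, cell_w = h / nrows, w / ncols
    types = rng.choice(len(PLANTATION_TYPES), size=n, p=np.asarray(type_shares))
    mills = rng.integers(0, 6, size=n)
    out = []
    for i in range(n):
        r, c = divmod(i, ncols)
        m_r = rng.uniform(0.08, 0.2) * cell_h
        m_c = rng.uniform(0.08, 0.2) * cell_w
        row0, row1 = r * cell_h + m_r, (r + 1) * cell_h - m_r
        col0, col1 = c * cell_w + m_c, (c + 1) * cell_w - m_c
        x0 = transform.x0 + col0 * transform.pixel_size
        x1 = transform.x0 + col1 * transform.pixel_size
        y0 = transform.y0 - row1 * transform.pixel_size
        y1 = transform.y0 - row0 * transform.pixel_size
        mill = int(mills[i])
        out.append(
            (
                box(x0, y0, x1, y1),
                {
                    "plantation_id": f"P{i:03d}",
                    "mill": f"M{mill + 1}",
                    "type": PLANTATION_TYPES[int(types[i])],
                    "certification_year": 2018 if mill < 3 else 2023,
                },
            )
        )
    return out


def generate_panel(spec: PanelSpec) -> tuple[pd.DataFrame, dict]:
    """Balanced plantation-year panel drawn from a known linear mixed model.

    coverage = intercept + X beta + b_i + eps, with b_i ~ N(0, ri_sd^2) per
    plantation and eps ~ N(0, res_sd^2). Regressors: plantation-type dummies
    (small-grower baseline), three index values, the annual price, and year
    dummies against the reference year. Returns (rows, truth record).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, years = spec.n_plantations, list(spec.years)
    betas = dict(DEFAULT_TRUE_BETAS)
    betas.update(spec.true_betas)

    types = rng.choice(len(PLANTATION_TYPES), size=n, p=np.asarray(spec.type_shares))
    cert = np.where(rng.random(n) < spec.share_certified_2018, 2018, 2023)
    b_i = rng.normal(0.0, spec.random_intercept_sd, n) if spec.random_intercept_sd > 0 else np.zeros(n)

    rows = []
    for i in range(n):
        tname = PLANTATION_TYPES[int(types[i])]
        for year in years:
            ndvi = rng.normal(0.70, 0.02)
            ndmi = rng.normal(0.986, 0.004)
            bsi = rng.normal(-0.745, 0.015)
            price = spec.prices[year]
            x = (
                betas["intercept"]
                + betas["self_produced"] * (tname == "own_estate")
                + betas["outsourced"] * (tname == "outside_supplier_estate")
                + betas["ndvi"] * ndvi
                + betas["ndmi"] * ndmi
                + betas["bsi"] * bsi
                + betas["price"] * price
                + betas.get(f"year_{year}", 0.0) * (year != spec.reference_year)
            )
            eps = rng.normal(0.0, spec.residual_sd)
            rows.append(
                {
                    "plantation_id": f"P{i:03d}",
                    "mill": f"M{(i % 3) + 1 + (0 if cert[i] == 2018 else 3)}",
                    "year": year,
                    "coverage": x + b_i[i] + eps,
                    "self_produced": int(tname == "own_estate"),
                    "outsourced": int(tname == "outside_supplier_estate"),
                    "type": tname,
                    "ndvi": ndvi,
                    "ndmi": ndmi,
                    "bsi": bsi,
                    "price": price,
                    "cohort": f"certified-{cert[i]}",
                }
            )
    panel = pd.DataFrame(rows)
    truth = {
        "betas": betas,
        "random_intercepts": b_i,
        "reference_year": spec.reference_year,
        "random_intercept_sd": spec.random_intercept_sd,
        "residual_sd": spec.residual_sd,
    }
    return panel, truth
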