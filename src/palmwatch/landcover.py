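"""Unsupervised land-cover classification with frozen k-means centroids.

One k-means model is fitted in 13-band reflectance space on a sample of
pixels from a single designated composite. Its clusters are then labelled
into land-cover classes (a manual step, externalized here as a
configuration mapping), the centroids are frozen, and every other tile-year
composite is classified by nearest centroid so coverage estimates stay
comparable across years. Plantation efficiency is the fraction of a
plantation's valid pixels classified as oil palm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .compositing import Composite
from .grids import BAND_NAMES
from .indices import pixels_in_polygon

#: Land-cover classes clusters may be labelled with.
CLASS_NAMES = ("oil_palm_mature", "oil_palm_immature", "other_vegetation", "other")

#: Classes counted as palm when measuring coverage (the default mode also
#: counts immature stands; a mature-only mode is available).
PALM_CLASSES = ("oil_palm_mature", "oil_palm_immature")

DEFAULT_K = 8
DEFAULT_SAMPLE_SIZE = 100_000


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, 13) reflectance
    labels: dict[int, str] | None = None
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count does not match k")

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "band_order": list(BAND_NAMES),
            "labels": {str(i): c for i, c in (self.labels or {}).items()} or None,
            "fit_metadata": self.fit_metadata,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        doc = json.loads(Path(path).read_text())
        labels = doc.get("labels")
        return cls(
            k=doc["k"],
            centroids=np.array(doc["centroids"]),
            labels={int(i): c for i, c in labels.items()} if labels else None,
            fit_metadata=doc.get("fit_metadata", {}),
        )


@dataclass
class CoverageRecord:
    plantation_id: str
    year: int
    coverage: float
    valid_pixel_count: int
    class_pixel_counts: dict[str, int]


def sample_pixels(
    composite: Composite, sample_size: int = DEFAULT_SAMPLE_SIZE, seed: int = 0
) -> np.ndarray:
    """Uniform random subsample of valid pixel band vectors, seeded."""
    stack = np.stack([composite.bands[b] for b in BAND_NAMES], axis=-1)
    vectors = stack[composite.valid_mask]
    vectors = vectors[~np.isnan(vectors).any(axis=1)]
    if vectors.shape[0] > sample_size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(vectors.shape[0], size=sample_size, replace=False)
        vectors = vectors[np.sort(idx)]
    return vectors


def fit_kmeans(pixels: np.ndarray, k: int = DEFAULT_K, seed: int = 0) -> ClusterModel:
    """Fit k-means in raw 13-band reflectance space (Lloyd, seeded).

    Features are unstandardized: after L2A-style scaling all bands share
    reflectance units. Returns an unlabeled model with inertia recorded.
    """
    pixels = np.asarray(pixels, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if pixels.ndim != 2 or pixels.shape[0] < k:
        raise ValueError(f"need at least k={k} sample vectors")
    if np.isnan(pixels).any():
        raise ValueError("sample contains nodata vectors")
    if np.allclose(pixels, pixels[0]):
        raise ValueError("degenerate sample: all vectors identical")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed, algorithm="lloyd")
    km.fit(pixels)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        fit_metadata={
            "sample_size": int(pixels.shape[0]),
            "seed": int(seed),
            "inertia": float(km.inertia_),
        },
    )


def label_clusters(model: ClusterModel, labeling: dict[int, str]) -> ClusterModel:
    """Attach a cluster -> land-cover-class map (the externalized manual step)."""
    missing = [i for i in range(model.k) if i not in labeling]
    if missing:
        raise ValueError(f"labeling is missing cluster indices {missing}")
    unknown_idx = [i for i in labeling if not (0 <= i < model.k)]
    if unknown_idx:
        raise ValueError(f"labeling names unknown cluster indices {unknown_idx}")
    bad = sorted({c for c in labeling.values() if c not in CLASS_NAMES})
    if bad:
        raise ValueError(f"unknown class names {bad}; expected one of {CLASS_NAMES}")
    return ClusterModel(
        k=model.k,
        centroids=model.centroids.copy(),
        labels=dict(labeling),
        fit_metadata={**model.fit_metadata, "labeling": {str(i): c for i, c in labeling.items()}},
    )


def label_clusters_by_truth(
    model: ClusterModel, composite: Composite, truth: np.ndarray,
    truth_to_class: dict[int, str],
) -> ClusterModel:
    """Label each cluster with the majority ground-truth class of its members.

    A synthetic-scene stand-in for hand labeling: only usable where a
    ground-truth class grid exists.
    """
    assign = assign_clusters(composite, model)
    labeling = {}
    for ci in range(model.k):
        member_truth = truth[(assign == ci) & composite.valid_mask]
        if member_truth.size == 0:
            labeling[ci] = "other"
            continue
        codes, counts = np.unique(member_truth, return_counts=True)
        labeling[ci] = truth_to_class[int(codes[np.argmax(counts)])]
    return label_clusters(model, labeling)


def assign_clusters(composite: Composite, model: ClusterModel) -> np.ndarray:
    """Nearest-centroid cluster index per pixel; -1 where nodata.

    Ties in Euclidean distance break to the lowest cluster index.
    """
    stack = np.stack([composite.bands[b] for b in BAND_NAMES], axis=-1)
    flat = stack.reshape(-1, len(BAND_NAMES))
    ok = ~np.isnan(flat).any(axis=1)
    out = np.full(flat.shape[0], -1, dtype=np.int32)
    if ok.any():
        d2 = ((flat[ok, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
        out[ok] = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    return out.reshape(composite.shape)


def classify_composite(composite: Composite, model: ClusterModel) -> np.ndarray:
    """Class-name grid from frozen centroids; '' where nodata. No refitting."""
    if not model.is_labeled:
        raise ValueError("model is unlabeled; call label_clusters first")
    assign = assign_clusters(composite, model)
    class_grid = np.full(composite.shape, "", dtype=object)
    for ci, cname in model.labels.items():
        class_grid[assign == ci] = cname
    return class_grid


def extract_coverage(
    class_grid: np.ndarray,
    transform,
    polygon,
    plantation_id: str,
    year: int,
    *,
    mode: str = "mature_plus_immature",
) -> CoverageRecord:
    """Count land-cover classes at pixel centers inside a plantation polygon.

    Coverage is the palm fraction of valid pixels; ``mode`` selects whether
    immature stands count as palm.
    """
    palm = PALM_CLASSES if mode == "mature_plus_immature" else ("oil_palm_mature",)
    inside = pixels_in_polygon(class_grid.shape, transform, polygon)
    cells = class_grid[inside]
    cells = cells[cells != ""]
    if cells.size == 0:
        raise ValueError(f"plantation {plantation_id}: zero valid pixels inside polygon")
    counts = {c: int((cells == c).sum()) for c in CLASS_NAMES}
    n_valid = int(cells.size)
    n_palm = sum(counts[c] for c in palm)
    return CoverageRecord(
        plantation_id=plantation_id,
        year=year,
        coverage=n_palm / n_valid,
        valid_pixel_count=n_valid,
        class_pixel_counts=counts,
    )
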