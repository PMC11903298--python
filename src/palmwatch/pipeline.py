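"""End-to-end orchestration: captures -> composites -> classes -> panel -> models.

The pipeline runs the published stage order on either synthetic scenes (the
default, no-download demonstration) or user-supplied rasters and polygons.
Every random draw flows from the single config seed through spawned child
seeds, so two runs with equal configs produce byte-identical CSV/JSON
artifacts. A JSON report records per-stage counts and fit summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compositing, indices as indices_mod, landcover, panel as panel_mod, synthetic
from .grids import write_geojson_features, write_raster

log = logging.getLogger("palmwatch.pipeline")

COVERAGE_MODES = ("mature_only", "mature_plus_immature")


@dataclasses.dataclass
class RunConfig:
    seed: int = 7
    output_dir: str = "palmwatch_out"
    years: tuple[int, ...] = synthetic.PanelSpec().years
    reference_year: int = 2018
    # synthetic scene
    scene_width: int = 120
    scene_height: int = 120
    cloud_fraction: float = 0.2
    noise_sd: float = 0.015
    n_captures: int = 3
    palm_decline_per_year: float = 0.0  # fraction of mature palm converted per post-reference year
    # plantations
    n_plantations: int = 12
    polygons_path: str | None = None
    prices_path: str | None = None
    # compositing
    tau: float = compositing.DEFAULT_TAU
    window_days: int = compositing.DEFAULT_WINDOW_DAYS
    # k-means
    k: int = 8
    kmeans_sample_size: int = 20_000
    labeling: dict[int, str] | None = None
    # downstream
    coverage_mode: str = "mature_plus_immature"
    year_dummies: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "years" in doc:
            doc["years"] = tuple(int(y) for y in doc["years"])
        if doc.get("labeling") is not None:
            doc["labeling"] = {int(i): c for i, c in doc["labeling"].items()}
        return cls(**doc)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations; empty iff the config is runnable."""
    v = []
    if config.tau <= 0:
        v.append(f"tau: must be > 0, got {config.tau}")
    if config.window_days <= 0:
        v.append(f"window_days: must be > 0, got {config.window_days}")
    if not 0.0 <= config.cloud_fraction <= 1.0:
        v.append(f"cloud_fraction: must be in [0, 1], got {config.cloud_fraction}")
    if config.noise_sd < 0:
        v.append(f"noise_sd: must be >= 0, got {config.noise_sd}")
    if config.k < 2:
        v.append(f"k: must be >= 2, got {config.k}")
    if config.n_captures < 3:
        v.append(f"n_captures: must be >= 3, got {config.n_captures}")
    if len(config.years) < 2:
        v.append("years: need at least 2 years")
    if config.coverage_mode not in COVERAGE_MODES:
        v.append(f"coverage_mode: must be one of {COVERAGE_MODES}, got {config.coverage_mode!r}")
    if config.scene_width <= 0 or config.scene_height <= 0:
        v.append("scene dimensions must be positive")
    if config.n_plantations < 1:
        v.append("n_plantations: must be >= 1")
    if not 0.0 <= config.palm_decline_per_year <= 1.0:
        v.append("palm_decline_per_year: must be in [0, 1]")
    if config.labeling is not None:
        missing = [i for i in range(config.k) if i not in config.labeling]
        if missing:
            v.append(f"labeling: missing cluster indices {missing} for k={config.k}")
        bad = sorted({c for c in config.labeling.values() if c not in landcover.CLASS_NAMES})
        if bad:
            v.append(f"labeling: unknown class names {bad}")
    for label, path in (("polygons_path", config.polygons_path), ("prices_path", config.prices_path)):
        if path is not None and not Path(path).exists():
            v.append(f"{label}: file not found: {path}")
    return v


def _declined_class_map(base: np.ndarray, order: np.ndarray, n_convert: int) -> np.ndarray:
    """Convert the first ``n_convert`` mature-palm pixels (in a fixed random
    order) to other vegetation: a cumulative, hence monotone, decline."""
    out = base.copy()
    flat = out.ravel()
    take = order[:n_convert]
    flat[take] = synthetic.TRUTH_CODES["other_vegetation"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute composite -> indices -> classify -> coverage -> panel -> models."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    scene_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    plant_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    kmeans_seed = int(seeds[2].generate_state(1)[0] % (2**31))
    year_seed_root = seeds[3]

    # --- scene ground truth -------------------------------------------------
    base_spec = synthetic.SceneSpec(
        width=config.scene_width,
        height=config.scene_height,
        cloud_fraction=config.cloud_fraction,
        noise_sd=config.noise_sd,
        n_captures=config.n_captures,
        seed=scene_seed,
    )
    rng = np.random.default_rng(scene_seed)
    base_map = synthetic._coherent_class_map(
        base_spec.height, base_spec.width, base_spec.class_shares, rng
    )
    mature = np.flatnonzero(base_map.ravel() == synthetic.TRUTH_CODES["oil_palm_mature"])
    decline_order = rng.permutation(mature)

    # --- plantations --------------------------------------------------------
    transform = None
    if config.polygons_path is not None:
        from .grids import read_geojson_features

        plantations = list(read_geojson_features(config.polygons_path))
    else:
        from .grids import GeoTransform

        transform = GeoTransform(600000.0, 620000.0, 10.0)
        plantations = synthetic.generate_plantations(
            config.n_plantations,
            (config.scene_height, config.scene_width),
            transform,
            seed=plant_seed,
        )
        write_geojson_features(out_dir / "plantations.geojson", plantations)
    plant_df = pd.DataFrame([props for _, props in plantations])
    report["stages"]["plantations"] = {"count": len(plantations)}

    prices = dict(synthetic.DEFAULT_PRICES)
    if config.prices_path is not None:
        table = pd.read_csv(config.prices_path)
        prices = dict(zip(table["year"].astype(int), table["price"].astype(float)))

    # --- per-year composites, indices, truth --------------------------------
    composites: dict[int, compositing.Composite] = {}
    truths: dict[int, np.ndarray] = {}
    ref = config.reference_year
    for year in config.years:
        n_post = max(0, year - ref)
        n_convert = int(round(config.palm_decline_per_year * n_post * mature.size))
        year_map = _declined_class_map(base_map, decline_order, n_convert)
        yseed = int(year_seed_root.spawn(1)[0].generate_state(1)[0] % (2**31)) + year
        spec = dataclasses.replace(base_spec, class_map=year_map, seed=yseed)
        captures, truth = synthetic.generate_scene(spec)
        comp = compositing.build_composite(
            captures, year=year, tau=config.tau, window_days=config.window_days
        )
        composites[year] = comp
        truths[year] = truth
    report["stages"]["composites"] = {
        "years": list(map(int, config.years)),
        "captures_per_year": config.n_captures,
    }

    # --- land-cover model ---------------------------------------------------
    fit_comp = composites[ref if ref in composites else config.years[0]]
    sample = landcover.sample_pixels(fit_comp, config.kmeans_sample_size, seed=kmeans_seed)
    model = landcover.fit_kmeans(sample, k=config.k, seed=kmeans_seed)
    if config.labeling is not None:
        model = landcover.label_clusters(model, config.labeling)
    else:
        model = landcover.label_clusters_by_truth(
            model, fit_comp, truths[fit_comp.year], synthetic.TRUTH_TO_LANDCOVER
        )
    model.to_json(out_dir / "cluster_model.json")
    report["stages"]["kmeans"] = {
        "k": config.k,
        "sample_size": int(sample.shape[0]),
        "inertia": model.fit_metadata.get("inertia"),
    }

    # --- classification, coverage, zonal indices ----------------------------
    palm_codes = (
        [synthetic.TRUTH_CODES["oil_palm_mature"], synthetic.TRUTH_CODES["oil_palm_immature"]]
        if config.coverage_mode == "mature_plus_immature"
        else [synthetic.TRUTH_CODES["oil_palm_mature"]]
    )
    cov_rows, idx_rows = [], []
    for year, comp in composites.items():
        class_grid = landcover.classify_composite(comp, model)
        grids = {
            name: indices_mod.compute_index(comp, name) for name in indices_mod.INDEX_NAMES
        }
        for geom, props in plantations:
            pid = props["plantation_id"]
            rec = landcover.extract_coverage(
                class_grid, comp.transform, geom, pid, year, mode=config.coverage_mode
            )
            row = {"plantation_id": pid, "year": year, "coverage": rec.coverage,
                   "valid_pixel_count": rec.valid_pixel_count}
            if year in truths:  # synthetic scenes carry ground truth
                inside = indices_mod.pixels_in_polygon(
                    truths[year].shape, comp.transform, geom
                )
                # truth at the same (valid) pixel centers the measurement used,
                # plus truth over the whole polygon for reference
                cells_valid = truths[year][inside & comp.valid_mask]
                row["truth_coverage"] = float(np.isin(cells_valid, palm_codes).mean())
                row["truth_coverage_all"] = float(
                    np.isin(truths[year][inside], palm_codes).mean()
                )
            cov_rows.append(row)
            row = {"plantation_id": pid, "year": year}
            for name, g in grids.items():
                row[name], _ = indices_mod.zonal_mean(g, geom)
            idx_rows.append(row)
        write_raster(
            out_dir / f"composite_{year}.tif",
            comp.bands,
            comp.transform,
            metadata={"tile_id": comp.tile_id, "year": int(year), **comp.metadata},
        )
    coverage_df = pd.DataFrame(cov_rows)
    index_df = pd.DataFrame(idx_rows)
    coverage_df.to_csv(out_dir / "coverage.csv", index=False)
    report["stages"]["coverage"] = {"rows": len(coverage_df)}

    # --- panel and models ---------------------------------------------------
    plant_df = plant_df.rename(columns={"certification_year": "certification_year"})
    panel = panel_mod.build_panel(coverage_df, index_df, plant_df, prices)
    panel.to_csv(out_dir / "panel.csv", index=False)
    report["stages"]["panel"] = {
        "rows": len(panel),
        "dropped": len(coverage_df) - len(panel),
    }

    fits = {}
    for cohort, sub in panel.groupby("cohort"):
        if sub["plantation_id"].nunique() < 2 or sub["year"].nunique() < 2:
            log.info("skipping cohort %s: too few plantations/years", cohort)
            continue
        try:
            fit = panel_mod.fit_random_effects(
                sub, include_year_dummies=config.year_dummies,
                reference_year=config.reference_year,
            )
        except ValueError as exc:
            log.warning("cohort %s: model not fitted (%s)", cohort, exc)
            continue
        fits[cohort] = fit.to_json()
    report["model_fits"] = fits

    by_type = [g["coverage"].to_numpy() for _, g in panel.groupby("type")]
    type_labels = [t for t, _ in panel.groupby("type")]
    if len(by_type) >= 2:
        h, df_, p = panel_mod.kruskal_wallis(by_type)
        dunn = panel_mod.dunn_posthoc(by_type, labels=type_labels)
        report["group_differences"] = {
            "kruskal_wallis": {"H": h, "df": df_, "p": p},
            "dunn": dunn.to_dict(orient="records"),
        }

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
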