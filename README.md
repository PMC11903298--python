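# palmwatch

Satellite-based measurement of oil-palm plantation efficiency, and panel
analysis of how that efficiency changes around sustainability-certification
events.

## The problem

Oil-palm producers do not publish per-plantation tree counts, so the effect
of certification schemes on plantation management has to be measured from
space. The measurement chain implemented here is:

1. **Cloud-free compositing.** A tropical tile is observed repeatedly; each
   capture comes with a provider cloud mask that misses some cloud. Residual
   cloud is screened by pixel-wise comparison of ≥3 near-simultaneous
   captures against their cross-capture median in the visible bands (the
   "delta" screen — clouds brighten blue and red), then surviving
   observations are merged per pixel with a median. All 13 multispectral
   bands are up-sampled to a common 10 m grid with a linear kernel.
2. **Land-cover classification.** One unsupervised k-means model is fitted
   in 13-band reflectance space on a single composite, its clusters are
   labelled into land-cover classes (mature oil palm, immature oil palm,
   other vegetation, other), and the centroids are then **frozen** and
   reapplied to every tile-year, so coverage estimates are comparable across
   years. Plantation efficiency for a polygon and year is the fraction of
   its valid pixels classified as oil palm.
3. **Spectral indices.** Per composite: NDVI = (B08−B04)/(B08+B04),
   NDMI = (B08−B11)/(B08+B11), and
   BSI = ((B11+B04)−(B08+B02)) / ((B11+B04)+(B08+B02)),
   averaged over each plantation polygon (pixel-center rule) as
   environmental controls.
4. **Panel models.** Per certification cohort, a linear mixed model fitted
   by maximum likelihood:

   coverage_it = β₀ + β·type_i + β·indices_it + β·price_t + γ_year + b_i + ε_it

   with a random intercept b_i per plantation, year dummies against a
   reference year, Wald two-tailed p-values, marginal/conditional R²
   (variance partition), and AIC/BIC from the ML log-likelihood. Coverage
   differences across plantation types are assessed with a Kruskal–Wallis
   rank-sum test and Dunn's post-hoc pairwise z tests (tie-corrected).

Because real rasters are bulky and access-controlled, the package ships a
first-class synthetic-data module: multispectral scenes with known
land-cover ground truth, imperfect cloud masks, and plantation-year panels
drawn from a known mixed model — every downstream stage is testable without
downloading anything.

## Worked example

```bash
palmwatch run --config demo.yaml
```

generates seven years (2017–2023) of synthetic tile scenes (120×120 px,
3 captures/year, 20 % cloud per capture) with a 3 %-per-year post-2018
decline in mature palm, 12 plantation polygons, and runs the full chain.
It prints the stage report:

```
"plantations": {"count": 12},
"composites":  {"years": [2017, ..., 2023], "captures_per_year": 3},
"kmeans":      {"k": 8, "sample_size": 13795, "inertia": 21.145},
"coverage":    {"rows": 84},
"panel":       {"rows": 84, "dropped": 0}
```

and writes `palmwatch_out/` with composites (TIFF + JSON sidecar), the
frozen cluster model, `coverage.csv`, `panel.csv` and `report.json`.
In `coverage.csv` the mean measured coverage falls from 0.675 (2017) and
0.651 (2018) to 0.576 (2023), tracking the injected decline; the worst
per-polygon disagreement with ground truth at the measured pixel centers is
0.0017. `report.json` carries the per-cohort mixed-model fits
(for this run, marginal R² 0.994 on the certified-2018 cohort, n = 28) and
the type comparison (Kruskal–Wallis χ² = 4.787, df = 2, p = 0.091 — with
only 12 random plantations the type effect is, correctly, not significant).

Individual stages are also exposed as CLI verbs (`simulate`, `composite`,
`indices`, `fit-kmeans`, `classify`, `model`, `groupdiff`, `validate`) and
as plain library functions (`palmwatch.generate_scene`,
`palmwatch.build_composite`, `palmwatch.fit_random_effects`, ...).

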