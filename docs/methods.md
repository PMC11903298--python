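# Methods

## Compositing model

A tile-year is represented by ≥3 co-registered captures taken within a
short window (default 15 days), each a 13-band reflectance stack with a
boolean cloud mask at 10 m. Assumptions: the land surface is unchanged
within the window; clouds are bright in the visible bands; provider masks
are imperfect.

**Up-sampling.** The 20 m and 60 m bands are interpolated to 10 m with a
bilinear (linear) kernel under pixel-center registration: target center *i*
maps to source coordinate (i + 0.5)/r − 0.5 for integer ratio r, edges
clamped. Nodata (NaN) contaminates every target pixel whose 2×2 stencil
touches it — a deliberate conservative rule. Up-sampling happens before the
cloud screen so masks and bands share one grid.

**Delta cloud screen.** For each capture, pixel and reference band (B02,
B04), the deviation from the per-pixel consensus is computed; the pixel is
flagged when it exceeds the consensus by more than τ (default 0.12
reflectance, configurable). Two choices matter and were made deliberately:

- the consensus is the median over captures *not already flagged by their
  provider masks*, so known cloud does not pull the consensus toward itself;
- the rule is **one-sided** (only positive deviations flag). Clouds
  brighten the visible bands; a symmetric rule discards the single clean
  capture at pixels where the other two captures are cloudy, because the
  clean value then deviates from a cloud-dominated consensus. With three
  captures this failure mode is common enough to corrupt coverage estimates
  by up to ~0.25 on synthetic scenes; the one-sided rule removes it.

**Merge.** Per pixel and band, the composite is the median over captures not
flagged by (provider ∪ delta) masks. The median is robust to residual
contamination and permutation-invariant, giving order-independent
composites. Before merging, each capture's combined mask is dilated by 2
pixels (3×3 structuring element) — standard cloud-mask buffering that
removes semi-transparent cloud edges below τ and isolated unflagged pixels
inside cloud patches. Provenance counts contributing captures; pixels never
seen cloud-free are nodata everywhere downstream.

## Land-cover model

k-means (Lloyd, seeded, 10 restarts) in raw 13-band reflectance space on a
uniform random subsample (default 100 000 pixels) of one designated
composite. Features are unstandardized: after L2A-style scaling all bands
share reflectance units, and rescaling would distort the spectral geometry
the clusters exploit. k defaults to 8 — the four reported class groups plus
within-class heterogeneity (at minimum k ≥ 4 is required to label four
classes). Cluster→class labelling is externalized as configuration (the
manual step of photo-interpretation); on synthetic scenes a majority-vote
labelling against ground truth stands in for it. Centroids are then frozen;
every composite is classified by nearest centroid (Euclidean), ties broken
to the lowest cluster index for determinism, nodata propagated.

Coverage counts both mature and immature palm classes by default (the
alternative mature-only definition is a config switch), over pixel centers
inside the plantation polygon.

## Indices and zonal statistics

NDVI, NDMI, BSI are computed elementwise on the 10 m composite; a vanishing
denominator yields nodata rather than a clamped ±1, since it only occurs on
degenerate or nodata pixels. Zonal means use pixel-center containment —
deterministic and exactly checkable against a point-in-polygon loop —
rather than area weighting; at 10 m against multi-hectare polygons the
difference is negligible. Per-year pooled index summaries can be weighted
by plantation (default) or by pixel.

## Panel model

One row per plantation-year: coverage, type dummies with the small-grower
category omitted, three index means, the annual price (constant within a
year), and a cohort label from the certification year. The model is a
linear mixed model with a random intercept per plantation, estimated by
**maximum likelihood** (not REML) so that log-likelihoods, AIC and BIC are
comparable across nested models; AIC = 2k − 2·logLik and
BIC = k·ln(n) − 2·logLik with k = #fixed effects + 2 variance parameters.
Marginal R² is var(Xβ̂)/(var(Xβ̂) + σ²_b + σ²_ε); conditional R² adds σ²_b to
the numerator. p-values are two-tailed Wald z.

**Year-dummy aliasing.** Because the price is constant within a year, a
full set of year dummies plus price is exactly collinear. The fitter drops
trailing year dummies until the design has full rank (for a 7-year panel
this removes the final year) and records them in the fit. Consequently a
data-generating year effect placed on the final year is not identifiable,
and the synthetic effect patterns place none there. Estimates of the
remaining year dummies are unbiased for their generating values.

If the ML solution sits on the zero group-variance boundary, the variance
Hessian is singular and the model degenerates to pooled OLS, which is the
exact ML fit in that limit; the fitter falls back accordingly.

Kruskal–Wallis uses the tie-corrected H with a χ² reference (df = groups−1).
Dunn's post-hoc z for groups i, j is
(R̄_i − R̄_j) / √[(N(N+1)/12 − ΣT/(12(N−1)))(1/n_i + 1/n_j)] with
T = Σ(t³ − t) over tie groups; positive z means the first group ranks
higher. p-values are unadjusted two-tailed normal by default, with an
optional Holm switch.

## Synthetic data: what it emulates, and what it does not

**Scenes.** A spatially coherent class map (smoothed white noise
thresholded at the cumulative class-share quantiles) over five classes:
mature palm (55 %), immature palm (10 %), other vegetation (15 %), bare soil
(12 %), water (8 %). Per capture: i.i.d. Gaussian band noise (σ = 0.015),
independently placed soft-edged elliptical cloud fields covering ~20 % of
the scene, cloud pixels blended toward a bright flat spectrum, and a
provider mask that deliberately omits 10 % of truly cloudy pixels — the
delta screen only matters if masks are imperfect, and how many residual
cloud pixels survive real provider masks is unknown; 10 % is a free
parameter, not an inference. Class spectra are configuration, not ground
truth: values sit in published typical reflectance ranges, with palm-canopy
SWIR set low so that scene-level index values land where observations of
producing plantations put them (vegetated NDVI ≈ 0.7, BSI ≈ −0.74, NDMI
near 1). Reflectances are clipped to [0, 1].

Not emulated: BRDF and topographic effects, atmospheric variability, cloud
shadows, mixed pixels at class boundaries, phenology, sensor artifacts.
Passing the recovery tests therefore shows the pipeline is correct and
robust to the modelled noise and occlusion — not that real Sentinel-2
scenes classify with 0.02 accuracy.

**Panels.** coverage = β₀ + Xβ + b_i + ε with b_i ~ N(0, 0.1²),
ε ~ N(0, 0.05²), type shares (28:39:77)/144, seven years, and an annual
price table anchored at the observed study-period extremes (1 940 MYR/t in
2018, 5 046 MYR/t in 2021; other years synthetic in-between values).
Default β: intercept −0.35, self-produced 0.04, outsourced −0.017, NDVI
0.75, NDMI 0.10, BSI −0.50, price 2×10⁻⁵ — chosen so typical coverage sits
near 0.7. The injected decline pattern runs from −0.08 (2019) to −0.252
(2022) on the coverage fraction, the magnitude reported for
certification-period declines. Generated coverage is not clipped to [0, 1]:
clipping would bias the recovery oracles, and with the default scales
excursions outside the unit interval are rare.

## Evaluation conventions

- End-to-end coverage recovery is judged against ground truth **at the same
  valid pixel centers** the measurement used. Truth over all polygon pixels
  is reported alongside (`truth_coverage_all`); the gap between the two is
  cloud-placement sampling, not classification error, and on single scenes
  it can reach several percentage points for small polygons under heavy
  cloud — a real limitation of annual composites that no classifier fixes.
- Null calibration of the year-dummy test is measured on one predeclared
  dummy (the first post-reference year) over 400 seeded replicates, judged
  against the binomial 95 % band around 5 %. Wald z tests on ML variance
  estimates are known to be slightly anticonservative at moderate group
  counts; at n = 96 plantations the measured rate stays within the band.
- Problem sizes used by the shipped tests and the acceptance script:
  120×120 px scenes, 3 captures/year, 7 years, 12 polygons for the raster
  chain; n = 96 plantations, 100 power replicates and 400 null replicates
  for the panel simulations. These sizes give stable Monte-Carlo estimates
  while keeping a full run in the minutes range on one CPU.

## Known limitations

- The delta screen assumes clouds brighten B02/B04; thin cirrus and cloud
  shadow (which darkens) are out of scope, as is B10-based cirrus
  correction.
- With all three captures cloudy at a pixel and the provider masks missing
  all of them, contamination can survive into the composite; at the default
  rates this is rare.
- Raster I/O is plain TIFF with a JSON sidecar for the geotransform and
  CRS; full GeoTIFF tag compliance is not attempted.
- The panel analysis is associational: no causal identification
  (difference-in-differences, matching) is attempted, and spatial
  autocorrelation between neighbouring plantations is not modelled.
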