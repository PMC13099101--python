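# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecopipe`, and what its synthetic-data validation does and does not
establish.

## Synthetic landscape generator

The generator produces an aligned raster stack on an `nrows × ncols` grid
(default 64×64 at 1 km cells) from one integer seed.  It emulates a
temperate continental monsoon region with strong west-east geomorphic
differentiation:

* **DEM** — a linear west→east decreasing trend (default 800 m excess in
  the west over a 100 m base) plus a Gaussian random field (white noise
  smoothed with a Gaussian kernel, σ = 3 cells, amplitude 250 m).  The
  trend/relief ratio makes the west-high/east-low gradient hold in
  essentially every seed while leaving realistic local relief.
* **Slope** — Horn's 3×3 finite-difference stencil on the DEM, in degrees,
  with edge replication at the border.  Degrees are used because management
  thresholds for slope are conventionally quoted in degrees.
* **Precipitation** — 0.7 weight on normalized elevation (orographic
  effect) plus an independent smooth field, min-max rescaled into the
  configured band, default 500–900 mm/yr.  **Temperature** — elevation
  lapse plus noise, rescaled to 12–16 °C.  **AET** — a smooth fraction of
  precipitation (mean 0.62, sd 0.08, clipped to [0.05, 0.95]) so water
  yield is positive but variable.
* **Rainfall erosivity** — `r = a·pre^b` with defaults `a = 0.05`,
  `b = 1.5`.  No specific regional erosivity formula is claimed; the power
  law is this package's explicit stand-in (zero at zero rainfall, strictly
  increasing, configurable coefficients).
* **Land use** — argmax over per-class suitability scores built from
  slope, elevation, precipitation and population covariates plus smoothed
  class-specific noise: cropland on flat low plains, forest on steep high
  ground, grassland intermediate, water in low wet cells, built-up around
  population maxima, unused land as residual patches.  Because every score
  term is spatially smooth, classes form autocorrelated patches.
* **NDVI, population, erodibility** — smooth fields correlated with
  precipitation (NDVI) and inverse elevation (population, squared for
  concentration), and an independent field rescaled to 0.10–0.40 for the
  erodibility factor.

All layers are deterministic functions of (config, seed); range
containment and the DEM gradient are tested properties.

## Ecosystem-service models

Seven services are computed per cell from the production equations listed
in the README.  Numerical decisions:

* **Water yield** is clamped at zero where AET exceeds precipitation;
  non-positive precipitation cells are flagged and masked.
* **Soil retention** implements the factor products exactly as written:
  potential loss `R·K·LS` and actual loss `R·K·C·P` *without* the
  topographic factor in the actual-loss term.  This makes negative
  retention possible where `C·P > LS`; such cells are counted in the
  layer's QC record rather than silently clamped (`usle_includes_ls=True`
  switches to the conventional USLE variant, `clamp_negative=True`
  clamps).  The identity `SEDRET ≡ PSLA − USLE` holds to machine
  precision by construction.
* **LS factor** uses the common raster form
  `(λ/22.13)^0.4 · (sin θ / 0.0896)^1.3` with slope length fixed at the
  cell size — no flow accumulation or routing is modelled anywhere in the
  package; that is an explicit scope boundary, not an approximation of a
  routed model.
* **Nutrient export** is a per-class lookup (load × delivery ratio) with
  an optional multiplicative load modifier (default 1).
* **Habitat degradation** `D` is the weighted sum over threat classes
  (cropland and built-up by default) of `exp(−d/decay)` with `d` the
  Euclidean cell distance to the nearest source cell, min-max normalized
  to [0,1] per run; quality follows the saturating response with
  `z = 2.5`, `K = 0.5`.  Monotonicity (more degradation never raises
  quality) is a tested property.
* **Food supply** is exactly conservative: the cropland NDVI-proportional
  shares sum to the configured regional total (default 6.5×10⁷ t, a
  large-province-scale grain output) to 1e−9 relative.
* The default carbon-pool and biophysical coefficient tables shipped under
  `src/ecopipe/data/` are synthetic defaults in the style of published
  per-land-use values; both are plain CSV and fully user-overridable.

## Pair classification

Spearman's coefficient is the Pearson correlation of tie-averaged ranks.
P-values: exact permutation enumeration for n ≤ 8, seeded Monte-Carlo
permutation (200k draws) for n = 9–10, and the t approximation above that.
FDR control uses Benjamini-Hochberg step-up jointly across all pairs;
significance is judged on adjusted p-values at α = 0.05.  Strength bins
|r| < 0.3 / 0.3–0.6 / > 0.6 (weak/moderate/strong) and the Fisher-z 95 %
CI are reporting conventions, configurable, with no inferential role.
Cells are the sampling unit; the analysis is confined to the grid scale.

## Bayesian belief network

* **Discretization**: continuous nodes get equal-frequency (quantile) bins,
  default 3 states; the extreme states are always labelled "low"/"high"
  (so scenario clamps are well-defined even when ties collapse bins); land
  use keeps its categorical codes.
* **Structure**: a two-layer DAG, factors → ES, with each ES node's
  parents a configurable list (defaults trim the plausibly-linked factors
  to ≤ 4 per ES for tractable CPTs at desk-scale sample sizes).  No
  structure learning and no inter-ES edges.
* **CPTs**: Laplace-smoothed counts, `P(s|pa) = (n_s + α)/(N + α|S|)`,
  α = 1; unseen parent configurations fall back to uniform.
* **Inference** is exact variable elimination; a full-joint enumeration
  oracle (independent code path) is used in tests, with agreement to
  1e−10 over random networks as the core correctness property.
* **Validation** follows the error-matrix protocol: a seeded 70/30 split,
  CPTs learned on the training rows, each ES predicted on test rows as the
  arg-max posterior given all other nodes.  With every non-target node
  observed the posterior reduces to the target's Markov blanket, which is
  computed in closed form (identical to elimination, vectorizable).
* **Variance reduction** `VR = V(Q) − E_F[V(Q|F)]`, with state values
  mapped to bin midpoints (categorical nodes use their codes).  The
  per-ES top-k VR ranking screens key factors; ties order by factor name.
* **Scenarios**: each significant synergy pair generates a both-high and a
  both-low clamp; each trade-off pair the two opposite-extreme clamps.
  Clamps are hard evidence on the named state.
* **Driver statistic**: |posterior − prior| changes of all factor-node
  states are pooled across scenarios (ES-node deltas are excluded from the
  pool); the threshold is the pooled 95th percentile (numpy linear
  interpolation), a factor is a driver when any of its changes strictly
  exceeds it, and the threshold's 95 % CI is the 2.5/97.5 percentile range
  of the statistic over 10,000 bootstrap resamples.  Synergy- and
  trade-off-scenario deltas are pooled together by default; per-relation
  pooling is a caller choice (pass the filtered delta table).

## Boosted trees, Shapley values, thresholds

* The classifier is second-order (Newton) boosting with logistic loss:
  per-leaf weight `−G/(H+λ)`, split gain
  `½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ`, exact greedy split
  search over midpoints of sorted unique values, gain ties broken to the
  lowest feature index then the lowest threshold (full determinism given
  the subsampling seed), `min_child_weight = 1` in Hessian units,
  base margin 0.  Hyperparameter search is a grid over the five standard
  knobs with stratified 3-fold CV maximizing macro-averaged F1.
* **Per-cell pair labels** (synergy = 1): concordance of median
  deviations — a cell is synergy when both ES layers sit on the same side
  of their medians.  Exact-median cells are dropped and counted.  This is
  the simplest rule consistent with "class 1 = synergy"; a local-window
  rank-correlation label is a possible alternative not implemented here.
* **Shapley values** use the interventional (marginal) value function: the
  mean model margin over a background sample with out-of-coalition
  features replaced by background values.  Attributions are in log-odds
  space.  Exact subset enumeration is refused above M = 12 features
  (a permutation-sampling estimator is provided); efficiency
  `ΣΦ = f(x) − mean_bg f` holds exactly by telescoping.
* **Curves**: 20 quantile bins (duplicate edges collapsed and counted),
  per-bin mean driver value, mean SHAP, CI half-width `1.96·sd/√n`; LOESS
  (tricube-weighted local linear, frac 0.5 over bins, as implemented in
  statsmodels) smooths the bin means.
* **Threshold detection**: crossings are linear-interpolated zeros between
  adjacent opposite-sign smoothed points; consecutive crossings closer
  than one (median) bin width merge into a sensitive interval.  Two gates
  keep no-signal inputs from reporting spurious reversals:
  1. a *significance gate* inside the detector — a sign change counts only
     when the smoothed curve exceeds the per-bin CI half-width somewhere
     within each adjacent sign run;
  2. a *skill gate* upstream — SHAP curves are only interpreted when the
     classifier shows out-of-sample skill (holdout AUC ≥ 0.55, about three
     standard errors above chance at the default test sizes).  A no-skill
     model's attributions are overfit noise: they are deterministic
     functions of the features with real amplitude, so no curve-level test
     can distinguish them from signal — model skill can.

## Planted ground truth and what recovery shows

* **Driver recovery** synthesizes the seven ES targets directly as
  `Σ effect·zscore(driver) + noise` (noise sd 0.5, |effect| 1.0) from two
  planted drivers (precipitation, slope), wires every null factor into at
  least two ES parent sets, and *decouples* the six null factors from the
  drivers by a seeded permutation of their cell values.  The decoupling is
  what makes "zero false positives" a well-posed target: in the raw
  generated landscape, erosivity is a deterministic function of
  precipitation and most layers share the terrain signal, so several
  "nulls" would be genuine statistical drivers.  Bypassing the production
  equations is likewise deliberate — their fixed algebra couples nearly
  all factors and admits no two-driver ground truth.
* **Threshold recovery** plants labels whose log-odds is an antisymmetric
  sigmoid step (sharpness 20, effect 3) through zero at x* = 0.6 of a
  rank-uniformized driver, made exactly zero-mean by concentrating the
  mean correction in the saturated tail.  Zero-mean matters: Shapley
  attributions are centred on the background mean, so only a zero-mean
  planted log-odds puts the attribution's sign reversal at x* itself (a
  mean-shifted construction would place it at the label-balance point, a
  different quantity).  Nuisance features are decoupled by permutation.

Passing these recovery sweeps shows the statistics separate signal from
noise *under the planted model*: linear/monotone effects, independent
nulls, moderate noise, stationary fields.  It does not show robustness to
confounded drivers, spatially autocorrelated residuals (which inflate
effective significance at the cell scale), non-stationary effects, or
misspecified network structure — all of which real landscape data have.
Real-data accuracy figures cannot be reproduced or checked from synthetic
landscapes; none are claimed.

## Problem sizes and defaults

The package's default experiment scales are: 64×64 demo pipeline
landscapes, 128×128 (16,384-cell) driver-recovery landscapes swept over
20 seeds, n = 2000 cells / 20 bins / LOESS frac 0.5 / 50-row SHAP
background for threshold recovery, 100 random networks for the inference
oracle, 10,000 bootstrap resamples for the driver threshold CI.  These are
the package's chosen desk-scale study conditions; every one of them is a
config field.

## I/O

Rasters are read and written as ESRI ASCII grids (plain text); tables as
CSV; networks, boosted-tree models and reports round-trip through JSON.
Grid metadata (cell size, origin, nodata) is carried through; no
projection handling is attempted.

## Known limitations

* No flow routing, sediment connectivity or Budyko-type water balance —
  the service models are per-cell factor algebra by design.
* Exact Shapley is exponential in features; above 12 features only the
  sampling estimator is available.
* Spearman p-values at n = 9–10 are Monte-Carlo rather than full
  enumeration (cost); at n ≤ 8 they are exact.
* The BBN assumes the given two-layer structure; structure error shows up
  as validation accuracy loss, not as a warning.
* Cell-level sampling treats cells as independent for inference; spatial
  autocorrelation makes nominal p-values optimistic on real rasters.
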