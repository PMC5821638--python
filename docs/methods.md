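# Methods

This note documents the statistical model behind `agbmc`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate, and
the numerical conventions that make results reproducible bit-for-bit.

## Error model and Monte-Carlo propagation

Plot-level field AGB is treated as carrying a single relative error
`eps_field`, the root-sum-square of three independent components:
tree-measurement error (default 10% — individual-tree errors average out
at stand level), allometric-model error (default 11%) and within-plot
sampling error. The sampling component follows from design arithmetic: a
±10% biomass estimate requires a 12.8% sampling intensity (160 subplots of
0.04 ha per 50 ha), hence 3.2 subplots per 1-ha pixel; four subplots give
`10·sqrt(3.2/4) ≈ 8.94%`. The default budget composes to 17.28%, used as
17% rounded in narrative text but at full precision in computation. The
assumption that the 50-ha variability transfers to a 1-ha pixel is adopted
as-is, not re-derived.

Propagation is non-parametric: `n` realizations (default 100, matching the
standard Monte-Carlo ensemble size of this workflow) of the plot AGB
vector, each `base·(1 + eps·X)` with i.i.d. standard-normal `X`. Negative
products are clipped to zero; at eps = 17% that is a ~6σ event and
numerically inert, but it guards configurations with larger errors. Each
realization is drawn from a counter-based sub-seed `(master_seed, r)`, so
any single realization can be regenerated independently and ensembles can
be parallelized without changing results.

Per-pixel uncertainty of an ensemble of predicted maps is summarized by
the empirical CI95 half-width `(q97.5 − q2.5)/2` (linear-interpolation
quantiles) and the relative uncertainty `100·CI95/mean`. Pixels whose
ensemble mean falls below a guard (default 1 t/ha) get no relative
uncertainty: the ratio diverges as the mean approaches zero, which is also
why relative uncertainties at low biomass dominate scene means.

## The learner

Both upscaling stages use a rule-based model tree: recursive binary
splitting on an SD-reduction (SSE) criterion, a multivariate least-squares
model at every node, bottom-up pruning that compares a node's
penalty-adjusted linear-model error `(n+v)/(n−v)·MAE` against its subtree,
and Quinlan smoothing at prediction time (leaf predictions blended with
ancestor models, weight `n_child/(n_child + k)`, k = 15). Predictions are
clamped to the training response range extended by 10% of that range —
the guard against linear-leaf extrapolation. Split ties break on lowest
predictor index, then lowest threshold, making fits fully deterministic.
Committee support (boosting-style response adjustment with averaged
predictions) exists but defaults to one member, since no committee count is
standard for this workflow. Defaults: `min_leaf_size` 20 (≥ 2·(p+1) for
the ~10-predictor problems here, keeping leaf models overdetermined),
`max_depth` 12, SD stop at 5% of the root SD.

Two behaviours of this learner matter scientifically: response
shift/scale equivariance (so results do not depend on units), and
mean-reversion — held-out extreme-biomass plots are pulled toward the
training mean, the reason biomass maps from tree ensembles underestimate
the top of the range and overestimate the bottom.

## Scenarios

* `nfi_direct`: plots (minus strip plots, minus slopes > 15°) are split
  67/33 into calibration/validation, stratified in 30 t/ha classes (ten
  classes, last open-ended, round-half-up per class). Each realization of
  calibration-plot AGB trains a model on the ten satellite layers;
  predictions cover the full grid.
* `lidar_two_stage`: plots whose pixel lies on the strips train stage 1 on
  the LiDAR metrics — after a residual screen that drops plots whose
  residual from a single fit against the un-noised mean response exceeds
  2×SD (the screen targets plots disturbed between field and airborne
  acquisition; the un-noised fit defines residuals because the noisy fits
  differ per realization). Stage-1 predictions at strip pixels become the
  training response of stage 2 on the satellite layers, realization r
  consuming realization r — the composition propagates, it never
  re-samples.
* `lidar_two_stage_screened`: identical, except strip pixels whose stage-1
  relative uncertainty is ≥ 50% (or undefined) are excluded from stage-2
  training.

Both masks are strict as a convention: forest is tree cover > 10%,
screening keeps uncertainty < 50%. Total aboveground carbon is
`Σ AGB·area·0.48` over forest pixels. Scenario reports log plot/pixel
counts at every filter step. Stage-2 training is capped at 4000 pixels
(deterministic draw from the run seed, the same subset for every
realization); the default scene's strips hold ~2000 pixels, so the cap only
binds on larger configurations.

## The synthetic scene

The generator produces planar rasters (no geodesy) with the statistical
structure this analysis assumes. Defaults, with rationale:

* **AGB field**: Gaussian random field with exponential covariance
  (spectral synthesis via FFT — deterministic given the seed, O(N log N)),
  affine-scaled to mean 45 t/ha, SD 35 t/ha, clipped to [0, 160] —
  a dry-to-subhumid forest landscape (clipping raises the realized mean to
  ~47 and trims the SD to ~32). Correlation length 500 m on 100-m pixels.
* **Plots**: a regular 700-m grid (841 plots on the default scene) with
  10 m Gaussian geolocation jitter (the magnitude of inventory geolocation
  error is not standardized; 10 m is a GPS-under-canopy figure). Each plot
  samples four subplot values at its pixel with 10% relative measurement
  noise; plot AGB is the subplot mean. Slope comes from the terrain layer;
  ~12% of plots land on slopes > 15° and are excluded from all training.
* **LiDAR strips**: vertical strips (width 5 px) covering 5% of the scene.
  This is deliberate: airborne campaigns sample a few percent of a
  territory, so the strip-level model trains on ~50 plots while the
  national model trains on ~450 — the order-of-magnitude training
  asymmetry that makes two-stage error propagation visible. Metrics follow
  `a_k·(AGB·u)^b_k + noise` with per-metric coefficients drawn once from
  hashed sub-seeds (adding a metric never shifts the others). The latent
  canopy factor `u` (CV 0.2) is shared by all metrics of a pixel: stands
  of equal biomass differ in structure, so even a perfect regression of
  metrics on AGB retains plot-level scatter. Per-metric noise is small
  (10% of signal SD) because plot-aggregated height metrics are precise
  but collinear — their predictive limit is structural scatter, not
  measurement noise. Twelve metrics keep the multi-predictor character
  without the full real-world metric catalogue.
* **Satellite layers**: dual-polarization L-band backscatter follows a
  saturating dB curve `A + B(1 − exp(−α·AGB))` evaluated in linear power
  and multiplied by 4-look gamma speckle (speckle is multiplicative in
  power, never applied in dB); optical bands are saturating monotone
  curves with small Gaussian noise; NDVI derives from red/NIR; tree cover
  is a noiseless logistic of AGB scaled to [0, 100] (midpoint 25 t/ha, so
  the >10% forest definition corresponds to AGB ≳ 7 t/ha); altitude and
  slope come from independent random fields.

### What passing tests do and do not show

The scene reproduces the *structure* of the real workflow's error
propagation: stage-1 strip uncertainties span ~12% to >200%, are largest
at low biomass while the absolute CI95 grows with biomass, the 2×SD screen
removes ~2–6% of strip plots, and the coherent part of the stage-1
ensemble spread passes through stage 2 essentially intact. It does not
reproduce the real magnitudes: the synthetic predictors are cleaner and
the forest more homogeneous than a real country, so map uncertainties sit
near 10% rather than 30–70%, and the 50% screen removes only ~25% of strip
pixels where the real workflow discarded ~75%. Consequently the screened
and unscreened two-stage runs train on nearly the same data, and their
scene-mean uncertainties can differ at noise level — the direction of that
particular comparison on a given seed is not a robust property of the
synthetic world, while `two-stage > direct` and the screened histogram
shift toward higher biomass are. Conclusions about real data should rest
on the structural properties, not the absolute synthetic numbers.

## Numerical conventions

* All randomness flows from one master seed through SHA-256 hashed
  component names (scene layers) or counters (realizations); identical
  configurations are byte-identical.
* dB ↔ linear conversion uses `10·log10`, flooring non-positive power at
  −50 dB. The speckle filter operates strictly in linear power with
  mirror-padded 7×7 local means; pixels with a non-positive local mean
  pass through unfiltered.
* Block aggregation averages trailing partial blocks over the cells
  present; nearest-neighbour aggregation anchors at the block's top-left
  pixel centre.
* Rasters persist as single-band float32 TIFFs with −9999 as nodata;
  scenes are directories of layers plus `plots.csv` and `scene.yaml`;
  zones serialize as GeoJSON; fitted trees serialize to JSON rule lists.
* Hexagon meshes are flat-topped, edge length from
  `A = (3√3/2)·s²`, clipped at the scene bounds. On the default scaled
  scene the validation examples use cells of a few km²; with real
  country-scale rasters the same code takes the standard 650 km².

## Limitations

Beyond the scene realism noted above: no spatial correlation in the field
error (components are independent per plot and realization); no covariance
between error components; no temporal dimension (single inventory
campaign, no change between field and airborne acquisition other than what
the residual screen emulates); no categorical predictors in the learner;
zone validation assumes each plot falls in at most one zone. The exact
rule-generation heuristics of the proprietary Cubist system are not
public; the M5-style tree with smoothing implemented here is a documented,
deterministic approximation exposed behind a learner interface so an
alternative regressor can be swapped in.
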