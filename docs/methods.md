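# Methods

This note documents the models, numerical choices and limitations of the
`firerisk` package in enough detail to reproduce or audit any stage.

## 1. Data model

All layers live on a shared `Grid`: row-major, origin at the outer corner
of the top-left cell, cell centers at `origin + ((col+0.5), −(row+0.5))·s`
with cell size `s` in km (default 1 km, the working resolution of the
analysis). A boolean nodata mask is part of the grid and is shared by every
layer; nodata propagates — any operation over a masked cell yields a masked
cell, never a silent zero. Rasters round-trip through ESRI ASCII grid and
GeoTIFF (written via `tifffile` with ModelPixelScale/ModelTiepoint/
GDAL_NODATA tags). Reprojection and non-integer resampling are out of
scope: aggregation from fine to coarse grids is only defined for integer
factors, and `aggregate_fraction` conserves the global mean exactly.

## 2. Covariates

* **MCWD** (maximum climatological water deficit, mm): the monthly water
  deficit accumulates as `WD_n = min(0, WD_{n−1} + P_n − T)` with the
  evapotranspiration proxy `T = 100` mm/month, starting from zero at a
  configurable `reset_month`; MCWD is the most negative deficit of the
  12-month window. The reset defaults to January, the climatological
  wettest month of the synthetic seasonality; no universal convention
  exists, so it is a parameter. MCWD is translation-covariant and
  identically zero when every month meets the threshold.
* **Anomalies**: departure of one year from the mean over all supplied
  baseline years (the baseline *includes* the target year, so an 11-year
  baseline 2000–2010 containing 2010 behaves as in multi-year satellite
  climatologies). Negative MCWD anomaly = drier than baseline; positive
  temperature anomaly = warmer. The per-cell mean anomaly over the baseline
  is exactly zero. The temperature covariate is the anomaly of the annual
  mean of monthly land-surface temperatures; integer-scaled LST inputs are
  decoded with the standard 0.02 K scale factor.
* **Road distance** (m): roads are rasterized by marking every cell a
  polyline touches (segments sampled at 1/8 cell); per class the Euclidean
  distance transform is multiplied by a class weight and the final layer is
  the minimum over classes. Defaults: paved 1.0, unpaved 0.5 — the smaller
  unpaved weight lets the dense secondary network dominate the combined
  distance, which is the empirically better predictor in fire-prone
  frontier landscapes. The exact functional form of a "weighted distance"
  is a design decision of this package; each class's unweighted field is
  1-Lipschitz on the grid.
* **Settlement density** (persons/km²): population-weighted 2-D quartic
  (biweight) kernel, `K(u) = 3/(πh²)·(1−u²)²` for `u = d/h ≤ 1`, bandwidth
  default 10 km. The kernel integrates to the total population (for points
  ≥ h from the boundary) and is additive in settlements. Kernel and
  bandwidth are conventions of this package; no canonical choice exists.
* **Land-cover / deforestation fractions**: share of fine-grid cells of a
  given categorical code (or of a binary change map) per coarse cell.

## 3. The maximum-entropy model

Features: per continuous variable — linear, quadratic, and forward+reverse
hinges at 4 evenly spaced quantile knots (products available but off by
default, mirroring the canonical auto-feature convention for large
samples); per categorical variable — one indicator per declared code. Every
feature is affinely scaled to [0, 1] over the background sample; constant
variables are dropped with a warning.

Fit: minimize `ln Z(λ) − f̄·λ + Σ βⱼ|λⱼ|` where `Z` sums `exp(λ·f)` over
background and `f̄` is the presence mean. The solver is FISTA (accelerated
proximal gradient) with backtracking line search, soft-thresholding for the
L1 term, and a monotone restart; it is deterministic. The iteration cap
defaults to 500 with convergence declared at a relative objective change
below 1e-6; non-convergence returns the model with `converged=False` and a
warning rather than an error. On well-posed tiny instances the fitted
weights agree with an independent convex optimizer (L-BFGS-B on the
split-variable reformulation) to 1e-4, and with β = 0 the feature
expectations match presence means to 1e-6 — the defining constraint of the
method.

Regularization: `βⱼ = multiplier × β_class(m) × sⱼ/√m`, with `β_class`
linearly interpolating the standard per-class tables in the presence count
m (linear/quadratic/product: 1.0 at m=10, 0.2 at 30, 0.05 at 100; hinge:
0.5; categorical indicator: 0.65/0.5/0.25 at 0/10/17) and `sⱼ` the feature
spread over presences, floored at 0.05 so every penalty stays positive.
The global multiplier defaults to 1.

Background: all unmasked cells when ≤ 10,000, else a seeded uniform sample
of 10,000; presence cells may appear in the background
(presence-background convention). Duplicate presences within a cell are
collapsed by default (toggle `collapse_duplicates`).

Outputs: *raw* — q renormalized over the prediction region; *logistic* —
`p = τe^H q/(1−τ+τe^H q)` with q on the training scale (`exp(η − ln Z_train)`),
τ = 0.5 and H the training entropy. Logistic is a strictly increasing
transform of raw, so rankings and AUC are identical. Projection clamps each
variable to its training range by default and reports the clamped-area
fraction.

Evaluation: presence-background AUC in rank-sum form (ties ½); a 25%
random test split; k-fold replicate models (default 10, 500 iterations
each) whose cell-wise mean map feeds the impact analysis; jackknife gains
(variable alone / omitted; regularized gain is zero for the uniform model);
percent contribution (solver gain increments allocated to variables by
their share of the weight update, products split evenly, normalized to
100); permutation importance (training-AUC drop after permuting one
variable across the pooled presence+background points, drops floored at 0
and normalized to 100); and a factorial group comparison with backward
elimination of variables whose omission changes the gain by less than a
tolerance (default 0.01).

## 4. Scenarios

A scenario names replacement layers for the dynamic variables only
(deforestation, roads, protected areas, temperature anomaly, MCWD anomaly)
plus a wet-year/dry-year climate tag; replacing anything else is a policy
error. "With climate change" substitutes the dry-year anomaly pair,
"without" the wet-year pair, mirroring a drought-analogue design in which
the model is calibrated on a dry year and validated on a wet one. Scenario
projection reuses the cross-validation replicate models, predicts with
clamping, and averages cell-wise. `apply_scenario` is side-effect free;
comparing a result with itself gives an exactly zero difference layer.
Specificity validation bins the projected probabilities at observed
presences (width 0.1) and reports the fraction above 0.5.

## 5. Impact accounting

Risk classes partition [0, 1] into low [0, 0.25), moderate [0.25, 0.5),
high [0.5, 0.75), extreme [0.75, 1] (half-open, top closed; p = 0.5 is
high). "High-risk area" uses the strict threshold p > 0.5. Potential
aboveground-biomass loss per cell above the threshold is
`B_l = (1 − α)·B_i` with the central estimate at the mean of the two loss
factors for α ∈ [0.7084, 0.90] (central factor 0.1958, half-range 0.0958)
and an envelope at the endpoints; multi-dataset AGB stacks are averaged
per cell *before* the loss formula (per-dataset bin means are also
reported — binning on the averaged layer is the default ordering).
Conversions are fixed at 1 km² = 100 ha and 1 Tg = 10⁶ Mg; AGB is dry
biomass, not carbon, and fire recurrence is not modelled. Per-bin reporting
uses width-0.1 probability bins. Zonal statistics (mean, SD, counts, areas,
area above threshold) are computed per category of any categorical zoning
layer; area-weighted zonal means recompose the global mean exactly.

## 6. Synthetic landscapes

The generator emulates the statistical structure of the real inputs so the
pipeline can be exercised against known ground truth:

* spatially autocorrelated fields by spectral synthesis (Gaussian spectrum,
  configurable length scales) for land-cover mosaics, biomass and climate
  modulation; categorical land cover and binary deforestation are drawn on
  a 4× finer grid and aggregated through the production operators
  (`landcover_fraction`, `aggregate_fraction`) — the generator never
  bypasses them, so full-loop recovery tests are meaningful;
* a sparse road network (2 paved + 6 unpaved jittered polylines),
  settlements placed preferentially near roads with lognormal populations,
  and a blocky 8-code protection layer;
* seasonal monthly rainfall with a July–November dry season (wet-season
  ~170, dry-season ~40 mm/month), one designated dry year (dry-season rain
  halved, +1.2 K warming) and one wet validation year; interannual
  variation carries spatial structure, as satellite anomaly maps do, so
  wet-year and dry-year anomaly ranges overlap and projection across years
  is interpolation for most cells;
* ground truth `p* = logistic(intercept + Σ w·standardized covariate)`,
  multiplied by an inhibition factor 0.5 inside protected blocks. Default
  weights make road proximity (−1.5 on distance), deforestation (+2.0) and
  settlement density (+1.0) the dominant drivers with a secondary climate
  control (+0.8 temperature anomaly, −0.8 MCWD anomaly) — chosen to mirror
  the empirical importance ranking in frontier fire regimes and the strong
  interannual climate control on fire-prone area;
* presences sampled with probability ∝ p*, months from a distribution
  putting 83% of records in August–September;
* scenario fixtures with ordering built in: A-like freezes deforestation
  and expands protection onto the most-pressured cells, B-like applies
  moderate road/deforestation growth, C-like strong growth, so high-risk
  areas order A ≤ B ≤ C by construction, and the dry variant swaps in the
  dry-year anomaly pair.

The default grid is 200×200 cells at 1 km so full pipelines run in minutes
on one CPU; parameter-recovery checks use a dedicated configuration
(`recovery_config`) with a single dominant independent driver
(deforestation +3, road pull removed, intercept −2).

What the generator does **not** emulate: true regional geometry, spatial
sampling bias in satellite fire detection, fire spread/contagion between
cells, temporally varying covariates within the training period, and
correlated AGB/land-cover structure. Passing tests therefore demonstrate
the correctness and calibration of the machinery — constraint satisfaction,
null AUC ≈ 0.5, recovery of known drivers, conservation laws, ordering of
constructed scenarios — not the real-world accuracy of any particular
regional fire-risk map.

## 7. Degenerate inputs and tie-breaks

Constant variables contribute no features; empty settlement sets yield a
zero density layer (an empty road set is an error — the distance covariate
is undefined); categorical layers must declare their codes and reject
undeclared ones; AUC requires both score sets non-empty; sample splitting
requires at least 4 records and forces at least one record on each side;
a single-variable jackknife degenerates to the full-model gain; empty
zonal categories are flagged rather than erroring. Maxent instances whose
presence mean sits on the boundary of the feasible moment polytope have no
finite optimum with β = 0; the regularized defaults (β > 0) avoid this.
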