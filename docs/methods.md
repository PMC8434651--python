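# Methods

`forestagb` implements an area-based workflow for estimating aboveground
biomass (AGB, Mg/ha) of natural secondary forests from airborne laser
scanning (ALS) and 7-band optical surface reflectance, evaluated end-to-end
on synthetic scenes whose ground truth is known. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Plot AGB from allometry

Individual-tree AGB follows the species-specific power law `W = a·D^b`
(`W` kg, `D` = DBH in cm). The packaged coefficient table has 18 rows for
the major tree and understory species of northeastern China; plantation
variants of *Larix olgensis*, *Pinus koraiensis* and *Pinus sylvestris* are
separate keys with a `_plantation` suffix, and the shared row for
*Fraxinus mandshurica* / *Juglans mandshurica* / *Phellodendron amurense*
is registered under all three names. Plot AGB density is the sum of tree
AGB over the plot divided by plot area (default 20 m × 30 m = 0.06 ha).
Trees below the 5 cm census threshold are rejected unless explicitly
allowed; the understory "arbor-like mixed species" row can act as a
fallback for unknown names but is off by default, since the census covers
trees ≥ 5 cm only.

## ALS preprocessing and plot metrics

* **Noise removal.** For each return, a least-squares plane is fitted to
  its horizontal neighbours within 0.5 m; the return is kept iff its
  distance to the plane is at most `max(1·SD, ε)` of the neighbours'
  residual SD (ε = 1e-9 keeps exactly coplanar neighbourhoods). Fewer than
  three neighbours ⇒ kept and logged. At survey densities near
  3.6 pts·m⁻² most neighbourhoods are small, so this filter is aimed at
  gross outliers (air/low points), not fine denoising.
* **DTM.** Inverse-distance-weighted interpolation of ground returns onto
  a 0.5 m grid (power 2, 12 nearest points); a cell center within 1e-9 m
  of a ground point takes its elevation exactly. Heights are normalized by
  subtracting the bilinearly sampled DTM. Synthetic clouds carry ground
  labels; for unlabelled data a lowest-point-per-cell fallback classifier
  is provided, which is deliberately simple and is *not* a progressive
  TIN densification filter.
* **Metrics** are computed over returns ≥ 2 m (the same threshold used for
  gap fraction; the cutoff is configurable). Families: elevation
  (mean, SD, CV, skewness, kurtosis, min/max/median, AAD, quadratic/cubic
  means, canopy relief ratio, percentiles 1, 5, 10, …, 95, 99), density
  (ten equal height slices of [2 m, max z], top slice closed), intensity
  (order statistics and percentiles, plus `int_AII_k` = cumulative
  intensity share of the lowest k % of returns ordered by height — an
  intensity-ordered variant is available behind a flag), and forest
  metrics (gap fraction = returns < 2 m / all returns; canopy cover =
  first returns ≥ 2 m / all first returns; LAI = −cos(θ_scan)·ln(gap)/k
  with extinction k = 0.5 and nadir scan assumed). Percentiles use linear
  interpolation between closest ranks everywhere. The enumeration is a
  documented superset (98 columns) reproducing every named headline
  metric; the exact composition used by commercial tooling is not public.

## Optical features

Reflectance is first topographically corrected with SCS+C:
`L_t = L·(cosθ·cosα + C)/(cos i + C)`, with `cos i` from slope, aspect and
the sun position, and `C` estimated per band as intercept/slope of the
regression of `L` on `cos i` over all unmasked pixels (deterministic; flat
terrain degenerates to the identity and `C` is set to 0). Derived layers:

* ten band combinations (MVI5, B76, B65, B53, MVI7, ND563, B54, B74, B43,
  ND67). ND563 is implemented as the normalized difference
  `(B5+B6−B3)/(B5+B6+B3)`; a literal product form is available behind a
  flag.
* fifteen vegetation indices (NDVI, EVI, ARVI, SAVI, MSAVI, OSAVI, DVI,
  RVI, GNDVI, NDMI, NBR, NDWI, GCI, VARI, EVI2) with the canonical
  literature constants (EVI G = 2.5, C1 = 6, C2 = 7.5, L = 1; SAVI
  L = 0.5; OSAVI L = 0.16).
* 56 GLCM textures: per band, eight Haralick statistics (mean, variance,
  homogeneity, contrast, dissimilarity, entropy with natural log and
  0·log 0 := 0, second moment, correlation) of a symmetric co-occurrence
  matrix accumulated over the four unit-distance directions, 32 gray
  levels quantized over the band's range, 3 × 3 window clipped at edges.
  Window size, level count and distance are configurable; none is fixed
  by published material.
* three principal components of the pixel × band matrix, ordered by
  explained variance with the largest-|loading| element of each component
  forced positive (a deterministic sign convention).

Plot sampling defaults to the pixel containing the plot center; an
area-weighted mean over the 20 m × 30 m rectangle is available for
sensitivity runs. Center sampling is the default because plot geolocation
error of a few meters makes sub-pixel weighting spurious at 30 m cells.

## Feature selection and COLI fusion

Selection is a two-step filter per source (ALS, optical): (1) keep
features whose Pearson correlation with AGB is significant at α = 0.05
(two-sided p from the t transform with n−2 df; zero-variance features are
excluded and logged); (2) rank survivors by random-forest impurity
importance over 10 seeded runs (seeds 0–9, 1000 trees at full budget) and
keep the k = 9 features with the lowest mean rank, ties broken by |r|
descending then name. "Most stable high-ranking set" has no canonical
definition; mean rank with declared ties is this package's
operationalization.

The best LiDAR variable (BLV) is the ALS metric whose univariate OLS
against AGB has the highest R² (exact ties to 1e-12 go to the first
column, logged). Fusion features pair the BLV with each selected optical
feature `SF_i`:

    COLI1_i = SF_i · BLV
    COLI2_i = (BLV − SF_i) / (BLV + SF_i)

Negative optical features are allowed; only vanishing denominators
(|BLV+SF| < 1e-12) yield NaN. Eight experiment feature sets are assembled
by id: F1 (9 ALS), F2 (9 optical), F1+2 (18), F4 (9 COLI1), F5 (9 COLI2),
F2+3 (optical + BLV, 10), F1+2+4 (27), F1+2+5 (27).

## Regression models

Eight base algorithms behind one fit/predict contract. Features are
standardized internally (training mean/SD) for ELM, BP, SVR, KNN and CNN;
targets are standardized for ELM, BP, SVR and CNN and predictions returned
on the original scale; tree models and MLR see raw features. Every
stochastic algorithm is seeded, so (spec, seed, data) fixes the fit.

| Algorithm | Core settings | Provenance |
|---|---|---|
| MLR | exact least squares, no regularization | baseline |
| ELM | 64 hidden units, sigmoid, hidden weights ~ U(−1,1) frozen, least-squares (pseudo-inverse) readout | hidden size/activation are package defaults |
| BP | one hidden layer (32 units, logistic), SGD with momentum 0.9, learning rate 0.01, 1000 epochs | epoch count is a protocol constant; width/rate are package defaults |
| RegT | CART, unconstrained depth, min leaf 1 | depth unconstrained is a package default |
| RF | 1000 trees, random state 10 | protocol constants |
| SVR | linear kernel, C = 1, ε = 0.1 | kernel/C are protocol constants; ε is a package default |
| KNN | k = 5, uniform weights | protocol constants |
| CNN | 1-D convolution over the feature vector (32 filters, width 3, ReLU), flattened map, dense output; Adam 1e-3, MSE, 1000 epochs, batch 30 | epochs/batch are protocol constants; the head and optimizer are package choices |

The CNN head uses flatten + dense rather than global average pooling:
pooling after a width-3 convolution averages away the position of a
feature in the vector and provably cannot represent a response driven by a
single feature column, which numerical checks confirmed. Flattening keeps
the architecture at one hidden layer while restoring position sensitivity.

## Stacked generalization

A two-layer stack: base models (default RF, SVR, KNN, CNN) feed a meta
model (any of the four) that consumes only the base predictions. Meta
training uses out-of-fold base predictions from a seeded inner K-fold
(K = 5): the base prediction for row i is always produced by a model whose
training excluded i's fold, so perturbing y_i cannot move row i's own meta
features. An in-sample variant (`inner="naive"`) is provided for
comparison and is known to leak. After meta fitting, bases are refit on
the full training set for deployment. Under outer leave-one-out
evaluation the entire inner procedure is repeated for every outer fold.

## Evaluation

Six indices over LOOCV prediction pairs: R² (squared Pearson correlation
of actual and predicted), RMSE, rRMSE = RMSE/ȳ, MAE, MAPE (%), and
PM = Σ(y−ŷ)²/Σ(y−ȳ)². A regression-SS variant
eq5_r2 = Σ(ŷ−ȳ)²/Σ(y−ȳ)² is reported alongside because it appears in the
literature; it is not bounded by 1 for biased predictions, which is why
the squared correlation is the headline R². Degenerate cases: any y = 0
makes MAPE NaN; constant actuals make PM/R² NaN; both warn.

LOOCV derives the fold seed as `master_seed + fold index`; failed folds
record NaN predictions and a coverage flag rather than aborting the grid.
Wall-to-wall prediction applies a trained model per pixel over
co-registered feature layers; pixels with any NaN feature become nodata
and negative predictions are clipped to 0 (the declared lower-bound rule).
Distribution comparison bins map pixels and plot actuals into half-open
50 Mg/ha bins and reports per-bin relative-frequency differences.

### Budgets

Two run profiles. `full` mirrors the headline hyperparameters above.
`small` is the desk-scale profile used by the test suite and the
acceptance script: RF 200 trees, CNN 100 epochs, BP 200 epochs, inner
stacking folds K = 3, and 200 trees in the selection ranking. The profile
changes cost only; every structural property (leakage safety, determinism,
orderings) is independent of it.

## Synthetic scenes

The generator emulates the field protocol: 20 m × 30 m plots, point clouds
at 3.6 pts·m⁻², per-tree species/DBH censuses, and reflectance that
saturates with biomass. Per plot: stem count ~ Poisson(60); species from a
configurable mixing table (default: a birch/oak/poplar-dominated broadleaf
mix with conifer admixture — a placeholder composition, since real stand
tables are site-specific); DBH ~ species Weibull truncated at 5 cm
(shape ≈ 2, scale 12–17 cm). True AGB is the allometric aggregate of the
tree list, so truth and the allometry module agree by construction.

Clouds: canopy top height H = h0·AGB^γ (h0 = 1.8, γ = 0.5; ~18 m at
100 Mg/ha), non-ground return heights ~ Beta(2, 1.2)·H, a 0.25 ground
fraction, intensity I0·exp(−k(H−z)) with k = 0.15 plus Gaussian noise, and
return numbers drawn categorically. Terrain is an optional uniform planar
slope (default flat; a few degrees suffices to exercise SCS+C), so the
DTM/normalization path always runs. Reflectance per band is
r0 + r1·exp(−AGB/s) + N(0, 0.01), clipped to [0, 1], with saturation
constants s between 70 and 110 Mg/ha — in the range reported for temperate
and subtropical forests — and band roles chosen so NIR brightens and
visible/SWIR darken with biomass. The raster fills space between plots
with a smoothed latent AGB surface and pins the cell containing each plot
center to that plot's true AGB.

All randomness flows through named per-plot substreams of one seed
(`default_rng([seed, stream, plot_index])`), so adding plots never
perturbs earlier ones and fixtures are byte-reproducible.

**What the synthetic experiments show — and don't.** Passing tests
demonstrate that the pipeline recovers a signal it is designed to see:
heights that scale monotonically with AGB, reflectance that saturates, and
noise that is Gaussian and independent across channels. Real forests add
occlusion, species-dependent reflectance, registration error, phenology
and sensor effects that the generator does not emulate, so synthetic
accuracy levels say nothing about accuracy on real acquisitions; only the
orderings (ALS > optical under saturation; adding the best LiDAR variable
helps optical models) and the structural guarantees (no leakage,
determinism, formula correctness) transfer.

## Problem sizes used by the checks

Formula and metric-engine oracles run on random inputs (clouds up to 5000
returns). Leakage checks use a 30-plot scene; signal recovery uses the
default 200-plot scene at seed 0; the feature-set ordering checks average
over ten 30-plot scenes; the determinism check reruns the full
3-set × 12-algorithm grid on a 30-plot scene with sharply reduced
hyperparameters, reproducibility being independent of model size. The
acceptance script evaluates representative cells (MLR, CNN, and the
RF-meta stack) on a 200-plot scene under the `small` profile.

## Known limitations

* The noise filter and the ground-classification fallback are simplified
  stand-ins for production point-cloud tooling; both are clearly labelled.
* The exact 101-metric and 98-feature enumerations of commercial/ENVI
  toolchains are not public; the implemented supersets reproduce every
  named feature but column-for-column parity is not claimed.
* Atmospheric correction, tasseled-cap and minimum-noise-fraction
  transforms are out of scope; the pipeline assumes surface reflectance.
* ALS metrics exist only at plot locations in the synthetic scene, so the
  wall-to-wall example maps an optical-feature model; mapping a fused
  model requires rasterized ALS metrics, which the generator does not
  produce.
* MAPE is undefined for zero-AGB plots; treeless plots are possible under
  the Poisson stem model and are reported as NaN with a warning.
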