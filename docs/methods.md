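# Methods

`firecarb` implements a bottom-up fire carbon accounting chain and a
synthetic-landscape generator that makes every stage of that chain testable
against known ground truth. This note records the models, the defaults and
the reasoning behind the design choices that were genuinely open.

## The estimation chain

Fire carbon release follows the classical bookkeeping product

    Cr = A × B × f_c × β

with burned area *A* (ha), biomass density *B* (Mg/ha), carbon fraction
*f_c* (default 0.5) and combustion completeness *β*. The chain estimates
*B* and *β* from remote sensing rather than biome-averaged lookup values:

1. **Field plots → LiDAR.** 0.09 ha plots (one per 30 m cell) calibrate a
   least-squares support-vector regression (LS-SVR) of aboveground biomass
   (AGB) on two canopy metrics: the area under the canopy pseudowaveform
   (AUCW, canopy material) and the median canopy height H50. Plots with GPS
   error above 2 m or fractional cover below 10% are excluded.
2. **Snag correction.** Fires leave standing dead trees whose top returns
   keep H50 high while canopy energy collapses, so the LiDAR model
   overestimates post-fire AGB. A power law `AUCW = a·H50^b` fitted on
   unburned cells supplies the expected canopy energy; every cell inside
   the fire perimeter gets `H50 ← min(1, AUCW/g(H50))·H50`. The weight is
   capped at 1 (fire only removes canopy) and cells on the curve are
   untouched.
3. **LiDAR → optical.** The (corrected) LiDAR AGB map trains per-date
   optical LS-SVR models (bands B2–B6, NDII, elevation) on ~514 pixels
   drawn from unburned and low-severity areas by histogram-stratified
   sampling, producing wall-to-wall pre-fire and post-fire AGB maps.
4. **Accounting.** Every map is de-biased by an observed-vs-estimated
   linear regression (dilution bias). Consumption is the pre−post map
   difference, aggregated to severity strata in Tg; carbon is 0.5× that,
   CO2-equivalent 44/12× the carbon. Combustion completeness per stratum is
   consumed over pre-fire stock, clipped to [0, 1].
5. **Uncertainty.** Step errors combine in quadrature
   (`σ² = RMSE₁² + RMSE₂²`, independence assumed). Stratum-mean standard
   errors honor spatial autocorrelation through an exponential correlogram
   fitted to the residual raster: `Var(mean) = σ²/n² ΣΣ ρ(d_ij)`, evaluated
   exactly via pair counts per distance class (FFT autocorrelation of the
   stratum indicator). Differences of correlated estimates use
   `Var(Δ) = Var₁ + Var₂ − 2 Cov` with the covariance estimated from paired
   residuals. Measurement, sensor and field errors are excluded as
   negligible against the modeling error.

## LS-SVR and model selection

Training solves the dual system `[[0, 1ᵀ],[1, K + I/γ]]·[b; α] = [0; y]`
with `K_ij = exp(−‖x_i−x_j‖²/h²)` on internally standardized features, so
predictions are invariant under affine rescaling of the inputs. The
bandwidth h and penalty γ come from a grid search (15 log-spaced values
each, h ∈ [0.1, 100] in standardized units, γ ∈ [0.1, 10⁴]) with 10-fold
cross validation, folds stratified over response deciles.

One selection subtlety matters enough to document. The CV error surface of
this two-hyperparameter family is extremely flat — dozens of (h, γ) pairs
lie within one standard error of the minimum — while the model's behavior
*outside the training support* varies enormously across that plateau. The
corrected H50 values of severely burned cells land exactly there: below
the lowest calibration plot, because plots with under 10% cover are
excluded by protocol. Plain CV-minimum selection therefore makes the
corrected map's low end essentially arbitrary. The LiDAR model instead
treats all pairs within one SE of the CV minimum as statistically tied and
resolves the tie with low-stature anchor points: positions on the
unburned H50–AUCW curve at H50 = 0.5, 1.5 and 3 m, with target AGB from a
power-law extrapolation of the calibration plots' own AGB–H50 trend.
Admissibility is judged on the chain *as deployed*: each candidate is
followed by its own dilution-bias line (refit from the plot pairs), and
must match every anchor within max(50% of the target, 10 Mg/ha) — the
bias-correction intercept jitters by ±10–15 Mg/ha at 65 plots, enough to
erase or double the corrected map's low range, so selecting on the raw
model alone is not sufficient. Among admissible candidates the best CV
error wins; if none qualifies the search widens once (1.5× the minimum)
before falling back to the least deviant candidate. This encodes one
physical fact — low-stature, low-energy cells hold little biomass,
continuously approaching zero — and is used only where anchors are
supplied; all other fits use plain CV minimization with ties broken toward
the smallest γ, then h.

Other fixed conventions: R² = 1 − SSE/SST (penalizes bias, unlike squared
correlation); RMSE = √(SSE/n); relRMSE = 100·RMSE/mean(observed); the
"combined" rows of fit tables pool calibration and validation predictions.
Stepwise feature selection uses entry/exit p-values 0.05/0.10 on linear
fits; the evolutionary selector is a small seeded genetic algorithm
(population 30, 25 generations, mutation 0.1) with CV-MSE fitness.

## LiDAR metrics

Heights are stored normalized (above ground); "canopy" means height > 2 m.
Percentiles use linear interpolation between order statistics; kurtosis is
Pearson (non-excess); skewness the standardized third moment. Intensity is
range-normalized by the inverse-square law before any energy metric; no
canopy/ground reflectance correction factor is applied. Pseudowaveforms
bin summed intensity in 0.5 m height bins spanning ground to the highest
return; the height of median energy (HOME) interpolates the mid-bin
cumulative energy curve, so a symmetric profile yields its midpoint. AUCW
integrates the canopy part of the waveform and is normalized by the pulse
count of the cell, making it density-invariant. The canopy height profile
uses the MacArthur–Horn transform with log arguments clipped at 10⁻⁶ of
total energy. Accumulated-intensity metrics are cumulative *fractions* of
canopy intensity (density-invariant); the density-weighted canopy
reflection sum divides the canopy energy by returns per m².

## The synthetic landscape

The generator emulates the observational setting of a Sierra Nevada
megafire and is the package's test bed; its defaults are the study
conditions and are not tuned per experiment.

* **Geometry.** 60×60 cells of 30 m including a 12-cell unburned buffer
  strip around the fire perimeter; severity inside the perimeter is
  assigned by thresholding a smooth random field at quantiles
  7.9 / 30.9 / 25.4 / 35.8% (unburned/low/moderate/high), so classes form
  spatial blobs with exact proportions. Vegetation types (conifer 60%,
  deciduous 10%, mixed 30%) form independent blobs. Elevation spans
  60–2400 m.
* **Biomass.** Cell AGB targets follow a lognormal field (mean 195.8,
  SD 143.1 Mg/ha, max 645.4) correlated with elevation, plus ~8% open
  meadow patches at 3–40 Mg/ha. Tree lists realize each target within 5%:
  diameters from a shifted gamma whose scale rises steeply with stand
  biomass (low-biomass stands are young and short, high-biomass stands
  few large stems — the diameter scale is 10 + 135·(AGB/645)^1.54 cm),
  heights from `H = 1.3 + a(1−e^(−b·DBH))^c`, and a power allometry
  `agb = α·DBH²·H` per species group standing in for the inventory
  equation library the real campaign used (only plot-level realism
  matters downstream). This makes AGB roughly a power ~1.1 of H50 across
  the landscape with H50 spanning ~3–31 m.
* **Point clouds.** ~20 pts/m² per cell; canopy returns are drawn from
  per-tree crown envelopes ([0.5H, H], biomass-weighted), ground returns
  near 0 m. Canopy cover rises essentially linearly with AGB
  (0.0022·AGB, capped at 0.95) with lognormal noise, so canopy energy
  tracks biomass without early saturation. Canopy reflectance at the
  laser wavelength varies cell-to-cell (lognormal, σ = 0.15), which makes
  AUCW a noisy biomass proxy and pushes the regression onto H50 — the
  same reliance that creates the snag overestimation in real data. Raw
  intensities carry the inverse-square range dependence of a constant-
  altitude flight over the terrain.
* **Fire effects.** True post-fire AGB is exactly (1−β_s)·pre with
  β = 0 / 0.30 / 0.50 / 0.85 by severity. The cloud loses the same
  fraction of canopy returns (they continue to the ground and become
  ground returns); the survivors are height-biased with severity —
  strongly top-biased in high severity (snags), where the topmost return
  always survives. H50 therefore stays high in snag cells while the
  canopy return count collapses by ≥ 70%.
* **Reflectance.** A linear mixture of vegetation, soil and (post-fire)
  char endmember spectra with cover as the vegetation weight, a small
  per-band elevation term and Gaussian sensor noise (σ = 0.010),
  clipped to [0, 1]. Burned cells show the NIR drop and SWIR rise of real
  burn scars, scaled by a char fraction of 0.35/0.65/0.90 per severity.
* **Plots.** 71 plots in the buffer: 65 placed uniformly over the biomass
  *range* (value-stratified, mirroring the stratified design of the real
  campaign and anchoring the sparse tails), 4 on near-bare cells (cover
  < 10%, to exercise the cover filter) and 2 with GPS errors above 2 m —
  so filtering deterministically retains 65.

What the generator does *not* emulate: radiative transfer, occlusion and
multiple returns per pulse, topographic illumination, phenology, plot
GPS-position error as an actual mislocation (it is a recorded attribute
only), and within-cell severity mixtures. Passing tests therefore show the
chain is internally correct and recovers truth under the stated error
structure, not that it would meet the same tolerances on any real fire.

## Numerical choices and degenerate inputs

Zero-intensity tiles yield zero energy ratios; cells without canopy
returns report zero canopy statistics but a normally computed cover ratio;
empty tiles are flagged nodata in metric rasters. Pseudowaveform energy is
conserved exactly (top bin edge inclusive). The correlogram is fixed to an
exponential `ρ(d) = e^(−d/φ)` fitted by least squares to the
pair-count-weighted empirical correlogram. Negative difference variances
are floored at zero with a warning. Negative AGB predictions are clipped
to zero with a logged count. Per-pixel negative consumption (independent
map noise) is *kept* in stratum sums so totals stay unbiased; a diagnostic
logs the negative fraction. Report tables round to 2 decimals only at
rendering.

All randomness flows from a single scene seed through fixed-purpose
`SeedSequence` children (per stage, per cell), so scenes, point clouds and
the whole pipeline are bit-reproducible; unburned cells reuse the same
structural draw on both dates.

## Problem sizes

The default scene is 60×60 cells (3600 cells ≈ 324 ha, ~65M simulated
returns streamed tile by tile, never held in memory at once), 71 plots and
514 optical training pixels; a full chain runs in about a minute on one
core. The chained-error validation uses twenty 24×24 unburned landscapes
with 250 optical samples and a 7×7 hyperparameter grid — small enough to
replicate, large enough that step errors are measured stably.

## Known limitations

* Recovery margins vary with the landscape realization. With the
  deployment-coupled anchored selection, the nine generator seeds
  exercised during development all satisfy the end-to-end recovery checks
  (total within 15%, per-stratum combustion completeness within ±0.1,
  median high-severity correction ≥ 70%), but several sit within a few
  points of a bound; the binding constraints are the model's behavior
  below the plot support (anchored, but still extrapolation) and the
  optical models' mild attenuation at the biomass-rich end.
* The correction weight equals the canopy energy ratio, which matches the
  consumed mass fraction only because cover is near-linear in AGB in the
  generator; in strongly cover-saturated forests the same construction
  would overcorrect.
* The two-step error composition `σ² = RMSE₁² + RMSE₂²` is a *conservative
  upper bound*, not an equality, for the chained estimator. The test suite
  measures this directly on repeated unburned landscapes: the empirical
  error of the chained optical prediction against truth falls short of the
  quadrature, with a negative correlation between the measured step errors.
  The mechanism is structural: RMSE₂ is measured against the noisy LiDAR
  reference, so it contains the part of the step-1 error that the optical
  features cannot see — but the fitted optical model smooths exactly that
  part away, and the final map never carries it. The corresponding test is
  intentionally left failing as a record of this property; the reported
  composed uncertainty should be read as an upper bound.
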