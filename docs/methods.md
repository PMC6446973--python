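# Methods

This note documents the models implemented in `chocoforest`, the synthetic
study system they are exercised on, and the numerical and design choices
made where the workflow left them open.

## The synthetic study system

No public lidar or inventory data exist for the study system the package
emulates, so the generator (`chocoforest.simulate`) is first-class code: it
defines the conditions under which every downstream claim is tested.

**Land cover.** A 30-m class mosaic is produced by quantile-thresholding a
smooth random field, which yields contiguous patches with exact target area
shares: 8 % nonforest, and the forest split 90.8 % terra firme / 7.8 %
wetland / 1.4 % mangrove. A configurable fraction of terra firme (default
37 %) is degraded, with a per-cell severity drawn smoothly from a uniform
range (default 0.1–0.8).

**Canopy height.** Heights are per-class affine transforms of a
standard-normal random field with exponential spatial correlation,
generated by circulant embedding (the covariance is laid out on a doubled
torus and white noise is filtered by the square-root spectrum). This makes
the realised correlation match the exponential model at the configured
range, which is what allows the semivariogram stage to recover the
generating range — a kernel-convolution construction would not close that
loop. Defaults per class: terra firme 21.8 ± 4.6 m, wetland 13.5 ± 7.9 m,
mangrove 16.5 ± 6.4 m, correlation range 150 m, generated at 5-m
resolution and replicated to the 1-m grid. Degradation multiplies height
by (1 − severity) and removes remaining emergent crowns where severity
exceeds 0.6. Class wood densities are 0.60 / 0.49 / 0.79 g cm⁻³.

**Predictors.** Seven 30-m bands emulate four optical reflectances, two
L-band radar backscatters and elevation. Each is a monotone function of
30-m mean height plus Gaussian noise; the HV-like band saturates above a
configurable height (default 25 m), reproducing the loss of radar
sensitivity over tall canopy that drives the map's uncertainty gradient.
Band noise SDs are calibrated jointly — once, as part of the study
conditions — so that scene-level leave-30 %-out cross-validation of the
height map attains R² ≈ 0.72 on the default landscape, the accuracy
observed with real predictor stacks of this kind. Radar bands can carry
nodata holes (topographic shadowing) via `radar_gap_fraction`.

**Sampling.** Lidar footprints are 1 km wide, 5/10/20 km long, headings
random at 45° intervals, placed by stratified random draw proportional to
stratum area with at least one scene per major stratum; footprints may
extend past the region (they are clipped at cell selection) but their
clipped areas must not overlap. Cluster plots follow the permanent-plot
design: one 1-ha plot plus eight 0.25-ha satellites at 250 m and 500 m in
the four cardinal directions; satellites outside the region are flagged
missing. Tree lists are drawn at 600 stems/ha (DBH ≥ 10 cm, shifted
exponential), labelled against a synthetic flora so that the taxonomic
identification mix is controllable (default 12 % species / 54 % genus /
24 % family / 10 % unidentified). Plot biomass follows the stand-in
allometry `AGB = a_true (TCH × WD)^{b_true}` times mean-one lognormal
noise, with stem biomasses (∝ WD · DBH^2.5) rescaled to sum to it — so the
parameter-recovery loop is exactly closed.

**What the generator does not emulate.** Radiometric realism, terrain
illumination effects, point-cloud-level lidar artefacts, wood-density
gradients within classes, and registration error between plots and lidar.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the pipeline under known truth, not the accuracy of any real
map.

## Canopy metrics

TCH is the arithmetic mean of the 1-m canopy-height pixels in each 100-m
cell (cells under 50 % valid coverage are nodata, threshold configurable);
PC is the percent of pixels strictly above 5 m; LCA binarises the canopy
strictly above 27 m, forms 4-connected components across the whole raster,
and counts pixels in components strictly larger than 100 m². Connected
components stand in for crown delineation: they are deterministic and
oracle-checkable, at the cost of merging adjacent tall crowns. Components
straddling cell borders are judged globally with pixels attributed per
cell. All three thresholds are strict as printed in the source
formulation; the 5-m cover threshold is exposed in the API.

## Biomass model

`AGB = a (TCH × WD)^b` is fitted by Levenberg–Marquardt nonlinear least
squares on untransformed biomass, start values (a, b) = (10, 1) — the
two-parameter surface is well-behaved over (a, b) ∈ [5, 40] × [0.5, 1.5]
and the start is immaterial there (property-tested). Leave-20 %-out
cross-validation resamples plots without replacement, refits per
iteration, and pools R²/RMSE/bias over concatenated held-out residuals;
diagnostics are invariant to plot ordering (plots are canonically sorted
before seeded resampling). Bias is mean(observed − predicted).

The replicated recovery experiment draws 43 plots with TCH ~ U(8, 35) m
and WD ∈ {0.60, 0.49, 0.79} in proportions 0.7/0.2/0.1, and applies
mean-one lognormal noise whose sigma is solved analytically from the
design moments so the expected fit R² equals the 0.72 target (solved, not
tuned: `noise_sigma_for_r2`). Bootstrap 95 % intervals are percentile
intervals over 200 refits on resampled plots.

## Height mapping

The 14-layer predictor stack is the 7 bands aggregated to 100 m plus the
7 texture layers (5×5-pixel population SD at native resolution — edge and
nodata-adjacent pixels use the valid sub-window — then aggregated).
Aggregation from 30 m to 100 m averages the fine cells whose centres fall
in each coarse cell.

The regressor is a scikit-learn random forest with the study's optimum
hyperparameters as defaults: 500 trees, one feature per split, minimum 13
samples per leaf. Cells with missing predictors are predicted from the
remaining layers by class-conditional median imputation (global median
fallback); this realises the required no-holes behaviour without surrogate
splits, which scikit-learn does not provide. Dilution bias (compression of
predictions toward the training mean) is corrected by regressing
out-of-bag predictions on observations, `oob = β₀ + β₁·obs`, and inverting
the line on the map; out-of-bag pairs are used rather than resubstitution
because they are the less optimistic choice. The correction is skipped
with a warning when |β₁| < 0.1. Training cells enter the final map only
through prediction (no pass-through of observed TCH), so over-fitting
artefacts over the lidar scenes remain visible, as they are in real maps
of this kind.

## Degradation

FDI sums quantities of mixed units (m + % + %) exactly as the source
formulation prints it; optional min-max normalisation of the components is
available but off by default. Thresholds come either from labelled
severity groups (midpoints between consecutive group medians, which must
ascend) or from explicit quantiles; the published threshold values are not
printed in the source, so the default quantiles (0.0474, 0.1426, 0.2609)
mirror the published class area shares of terra firme (severe 4.7 %,
+ moderate-to-high 14.3 %, + light 26.1 %). On synthetic data the class
boundaries are therefore reproducible; on real data they would need
re-calibration against labelled degradation gradients. Emission factors
are intact-minus-class mean biomass; regional loss is the area-weighted
sum, and both the land-cover (2-class) and index (4-class) classifications
are reported side by side with a cross-tabulation.

## Uncertainty

The per-pixel composition is exact quadrature of three terms. σ_RS is the
per-pixel SD across scene-resampled bootstrap maps (30 % of scenes
removed, 100 iterations by default; scenes, not cells, are the resampling
unit). σ_field is 21.4 % of pixel biomass. σ_modeling is apportioned
relative to biomass (model CV RMSE over mean calibration biomass, times
pixel biomass) because lidar-biomass residuals scale with stand size; an
absolute mode (RMSE everywhere) is provided. Height-map uncertainty uses
σ_RS only.

The class-variance formula is implemented with the 1/(m(m−1)) prefactor as
printed in the source, although the classical correlated-mean variance
would use 1/m²; a `convention` switch selects either, with the printed
form as default (fidelity first — the printed form exceeds the classical
one by the factor m/(m−1) and its documented consequence at full
correlation, σ²(1/(m−1)+1), is asserted numerically in the tests).
ρ(d) = 1 − γ(d)/(c₀+c₁) from the fitted exponential semivariogram, clamped
to [0, 1] and zeroed beyond three times the fitted range. The exact double
sum is evaluated for class sizes up to 5 000 pixels; above that, pairs
from a 5 000-pixel subsample are binned by distance, ρ evaluated at bin
means, and the pair sum rescaled to the full m(m−1) population — agreeing
with the exact sum to well under 1 % on tested instances.

Leave-one-scene-out jackknife reports per-scene and pooled metrics; the
mean per-iteration R² is typically below the pooled R² (small scenes have
little internal variance to explain) and both are reported without
asserting an ordering.

## Problem sizes

The demonstration region is 6 km × 6 km (a 36-million-pixel 1-m canopy
model, 3 600 analysis cells) with five 500-ha scenes — large enough for
the map CV, the uncertainty gradient over tall canopy and the degradation
gradient to be resolved, while the full analysis completes in well under
fifteen minutes on a single CPU. Unit tests use 0.6–4.5 km regions. The
variogram closed loop uses a 7.5-km domain for a 500-m range (the
empirical variogram needs the domain to be an order of magnitude larger
than the range for a stable sill).

## Known limitations

* Connected-component LCA merges adjacent tall crowns; it is a proxy for
  crown delineation, adequate for a cell-level percentage.
* Median imputation reproduces the behaviour (no nodata holes), not the
  mechanics, of surrogate splits; predictions in masked areas lean on the
  class map.
* The class-variance subsampled mode assumes the subsample's pair-distance
  distribution represents the class; elongated classes at large m are the
  worst case.
* Synthetic plot biomass is generated from the same functional form the
  model fits; real-world model misspecification is out of scope of the
  closed loop.
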