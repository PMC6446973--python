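# chocoforest

Forest structure, aboveground biomass and degradation mapping for tropical
forest carbon accounting, built around the workflow used for the Chocó
region of the Colombian Pacific coast: airborne-lidar canopy height models
calibrate a wood-density-aware biomass model, a random forest extrapolates
height wall-to-wall from satellite predictors, a structural degradation
index grades terra firme forest, and errors are propagated to per-pixel and
per-class uncertainties. Because the original lidar scenes and plot
inventories are not public, the package ships a synthetic-landscape
generator with known ground truth, so every stage runs — and is validated —
in a closed loop.

It is written for remote-sensing and forest-carbon researchers (REDD+
reporting, degradation assessment) who need a tested, reusable
implementation of this pipeline rather than a one-off collection of
scripts.

## The models

**Height to biomass.** Plot aboveground biomass (Mg/ha) follows a power law
in the product of mean top canopy height and plot-mean wood density,

```
AGB = a (TCH × WD)^b
```

fitted by nonlinear least squares and evaluated with leave-20%-out
cross-validation (1000 iterations by default). The reference fit used
throughout is `a = 17.8`, `b = 1.0`. With a unit exponent and
class-constant wood density, the class mean of the biomass map equals the
model at the class mean height — e.g. terra firme: `17.8 × 21.81 m ×
0.60 g cm⁻³ = 232.93 Mg/ha`.

**Degradation index.** For every 1-ha terra firme cell,

```
FDI = TCH + LCA + PC
```

where TCH is mean top canopy height (m), LCA the percent area under large
crowns (height > 27 m, crown area > 100 m²) and PC the percent cover above
5 m. Three ascending thresholds cut the index into severe,
moderate-to-high, light and intact classes; emission factors are the
differences between intact and per-class mean biomass.

**Uncertainty.** Per pixel, `σ²_total = σ²_RS + σ²_modeling + σ²_field`:
the spread of scene-resampled bootstrap predictions, the lidar-model error
apportioned by biomass, and a 21.4 % field/allometry term. Class-level
standard errors integrate the pixel sigmas with the spatial correlation
ρ(d) of a fitted exponential semivariogram,

```
σ²(class) = 1/(m(m−1)) · ( Σᵢ σ²ᵢ + 2 ΣΣ_{i<j} ρ(d_ij) σᵢ σⱼ )
```

Validation is scene-based throughout (leave-30 %-of-scenes-out and a
leave-one-scene-out jackknife), which keeps spatial autocorrelation from
leaking between training and test cells.

## Worked example

```python
from chocoforest import PipelineConfig, run_pipeline
from chocoforest.simulate import SimulationConfig
from chocoforest.height_map import EnsembleConfig

cfg = PipelineConfig(
    simulation=SimulationConfig(size=(6000.0, 6000.0), seed=11),
    n_scenes=5, rf=EnsembleConfig(n_trees=500, seed=11), seed=11,
)
res = run_pipeline(cfg)
print(f"AGB = {res.model.a:.2f} (TCH x WD)^{res.model.b:.3f}")
print(f"map CV: R2 = {res.cv_report.pooled_r2:.3f}")
print(res.summaries["fdi"].round(2))
```

prints (6 km × 6 km synthetic region, five 500-ha lidar scenes):

```
AGB = 18.92 (TCH x WD)^0.996
map CV: R2 = 0.730
           class  area_ha  mean_height  sd_height  mean_agb  sd_agb
          severe    143.0         7.25       4.25     82.05   47.23
moderate_to_high    286.0        11.00       4.87    123.87   54.57
           light    355.0        12.46       4.31    140.15   48.34
          intact   2219.0        20.62       4.36    231.54   48.73
```

The fitted coefficients recover the generating allometry (a_true = 17.8,
b_true = 1.0) within their bootstrap intervals; the scene-level CV R² of
~0.73 reflects the calibrated predictor noise; and the degradation classes
reproduce the built-in severity gradient (intact cells average 231.5 Mg/ha
against 82.1 Mg/ha in the severe class).

The same analysis is available as numbered drivers under `analysis/`
(`01_simulate_landscape.py` … `06_uncertainty_validation.py`), each of
which writes its tables to `results/`, and as a CLI
(`chocoforest run-all --out results --seed 11`, with per-stage subcommands
`simulate`, `metrics`, `fit-model`, `map-agb`, `degrade`).

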