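"""End-to-end orchestration: simulate -> metrics -> inventory -> model ->
height map -> biomass map -> degradation -> uncertainty -> reports.

The pipeline is a pure function of (config, seed): identical reruns
reproduce every map and table bit-for-bit. Each stage logs one structured
line with its parameters and headline outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import agb_model as am
from . import degradation as dg
from . import height_map as hm
from . import inventory as inv
from . import metrics as cm
from . import simulate as sim
from . import uncertainty as unc
from .raster import GridRaster
from .taxa import SyntheticTaxonomy

log = logging.getLogger("chocoforest")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "summarize_classes", "confusion_report", "make_height_pipeline"]


@dataclass
class PipelineConfig:
    """Single config governing all stages. Loadable from a YAML file."""

    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    n_scenes: int = 6
    scene_lengths: tuple[float, ...] = (5000.0,)
    n_clusters: int | None = None
    plot_noise_cv: float = 0.15
    cv_iterations: int = 200
    rf: hm.EnsembleConfig = field(default_factory=hm.EnsembleConfig)
    bootstrap_iterations: int = 25
    bootstrap_fraction: float = 0.3
    fdi_quantiles: tuple[float, float, float] = (0.0474, 0.1426, 0.2609)
    field_rel_error: float = 0.214
    variogram_max_lag: float = 1500.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        simcfg = sim.SimulationConfig(**raw.pop("simulation", {}))
        rfcfg = hm.EnsembleConfig(**raw.pop("rf", {}))
        for key in ("scene_lengths", "fdi_quantiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=simcfg, rf=rfcfg, **raw)


@dataclass
class PipelineResult:
    truth: sim.LandscapeTruth
    metrics: cm.HectareMetrics
    scenes: list[sim.SceneFootprint]
    plots: list[sim.PlotRecord]
    trees: list[sim.TreeRecord]
    model: am.AGBModel
    height_map: GridRaster
    agb_map: GridRaster
    fdi: dg.FDIResult
    uncertainty: unc.UncertaintyStack
    cv_report: unc.CVReport
    summaries: dict[str, pd.DataFrame]
    bias_info: dict
    calibration_plots: list[sim.PlotRecord] = field(default_factory=list)


def make_height_pipeline(config, truth, tch, stack, class100):
    """A callable scene-subset -> height map, for the CV/bootstrap schemes."""

    def run(scene_subset: Sequence[sim.SceneFootprint]) -> GridRaster:
        training = hm.assemble_training(tch, list(scene_subset), stack)
        hmap, _, _, training = hm.train_predict_height(
            training, stack, config.rf, class_map=class100
        )
        hmap, _ = hm.bias_correct(
            hmap, training["oob_pred"].to_numpy(), training["tch"].to_numpy()
        )
        return hmap

    return run


def _class_map_at(class_map: GridRaster, grid: GridRaster) -> GridRaster:
    """Majority-free nearest sampling of the 30-m class raster at 100-m centres."""
    xs, ys = grid.cell_centers()
    jx = ((xs - class_map.origin[0]) / class_map.cell_size).astype(int)
    jy = ((class_map.origin[1] - ys) / class_map.cell_size).astype(int)
    jx = np.clip(jx, 0, class_map.shape[1] - 1)
    jy = np.clip(jy, 0, class_map.shape[0] - 1)
    vals = class_map.values[np.ix_(jy, jx)]
    return GridRaster(vals, grid.cell_size, grid.origin)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a synthetic landscape."""
    t0 = time.time()
    seed = config.seed
    cfg = config.simulation

    def stage(name, **kw):
        log.info("stage=%s t=%.1fs %s", name, time.time() - t0,
                 " ".join(f"{k}={v}" for k, v in kw.items()))

    truth = sim.simulate_landscape(cfg)
    stage("simulate", size=cfg.size, seed=cfg.seed)

    chm = cm.CanopyHeightModel(truth.height_true)
    metrics = cm.hectare_metrics(chm)
    stage("metrics", cells=metrics.tch.shape)

    scenes = sim.sample_scenes(truth, config.n_scenes, seed=seed + 1,
                               lengths=config.scene_lengths)
    stage("scenes", n=len(scenes))

    design = sim.ClusterDesign(noise_cv=config.plot_noise_cv)
    taxonomy = SyntheticTaxonomy()
    plots, trees = sim.simulate_plots(truth, scenes, design, seed=seed + 2,
                                      n_clusters=config.n_clusters,
                                      taxonomy=taxonomy)
    wd_table = inv.WoodDensityTable(taxonomy.wood_density_rows())
    plot_classes = {p.plot_id: p.forest_class for p in plots}
    class_means = {c: SyntheticTaxonomy.class_mean_wd(c) for c in set(plot_classes.values())}
    tally = inv.assign_wood_density(trees, wd_table, class_means, plot_classes)
    stage("inventory", plots=len(plots), trees=len(trees), tally=dict(tally))

    kept = inv.colocate_with_lidar(plots, truth.height_true)
    one_ha = [p for p in kept if p.side == 100.0 and p.agb is not None]
    agg, _ = inv.aggregate_quarter_plots(kept)
    calib = one_ha + [p for p in agg if p.tch_lidar is not None]
    model = am.cross_validate_model(calib, iterations=config.cv_iterations, seed=seed + 3)
    model.mean_calibration_agb = float(np.mean([p.agb for p in calib]))
    stage("fit-model", a=round(model.a, 3), b=round(model.b, 3),
          r2=round(model.r2, 3), n=model.n_plots)

    bands = sim.simulate_predictors(truth, cfg)
    stack = hm.build_predictor_stack(bands, cell=100.0)
    class100 = _class_map_at(truth.class_map, metrics.tch)
    training = hm.assemble_training(metrics.tch, scenes, stack)
    hmap_raw, spread, rf, training = hm.train_predict_height(
        training, stack, config.rf, class_map=class100
    )
    hmap, bias_info = hm.bias_correct(
        hmap_raw, training["oob_pred"].to_numpy(), training["tch"].to_numpy()
    )
    stage("map-height", rows=len(training), bias=bias_info)

    wd100 = _class_map_at(truth.wd_map, metrics.tch)
    wd100.mask = _class_map_at(
        GridRaster(truth.wd_map.mask.astype(float), truth.wd_map.cell_size,
                   truth.wd_map.origin), metrics.tch
    ).values > 0.5
    agb_map = am.apply_model(model, hmap, wd100)
    stage("map-agb")

    tf_mask = np.isin(class100.values, sim.TERRA_FIRME_CODES)
    fdi_map = dg.compute_fdi(metrics.tch, metrics.lca, metrics.pc, tf_mask)
    thresholds = dg.calibrate_thresholds(
        fdi_map.values[fdi_map.mask], quantiles=config.fdi_quantiles
    )
    fdi = dg.classify_degradation(fdi_map, thresholds, height=hmap, agb=agb_map)
    stage("degrade", thresholds=thresholds)

    height_pipe = make_height_pipeline(config, truth, metrics.tch, stack, class100)
    _, sigma_rs_h, cv_report = unc.bootstrap_map_uncertainty(
        scenes, height_pipe, metrics.tch,
        fraction=config.bootstrap_fraction,
        iterations=config.bootstrap_iterations, seed=seed + 4,
    )
    # convert height sigma to AGB sigma through the (near-linear) model
    sigma_rs_agb = GridRaster(
        np.abs(model.predict(np.maximum(hmap.values, 0) + sigma_rs_h.filled(0.0), wd100.values)
               - agb_map.values),
        agb_map.cell_size, agb_map.origin, agb_map.mask & sigma_rs_h.mask,
    )
    stack_unc = unc.compose_pixel_error(
        sigma_rs_agb, model, agb_map, field_rel_error=config.field_rel_error
    )
    stage("uncertainty", iters=cv_report.n_iterations)

    try:
        sv = unc.fit_semivariogram(stack_unc.sigma_total, config.variogram_max_lag,
                                   seed=seed + 5)
    except ValueError:
        sv = unc.Semivariogram(0.0, 0.0, 1e-6, degenerate=True)

    summaries = {
        "lulc": summarize_classes(hmap, agb_map, class100, stack_unc, sv),
        "fdi": fdi.summary,
        "confusion": confusion_report(class100, fdi.class_raster),
        "loss_fdi": dg.biomass_loss(fdi.summary),
    }
    stage("report", wall=round(time.time() - t0, 1))
    return PipelineResult(truth, metrics, scenes, plots, trees, model, hmap,
                          agb_map, fdi, stack_unc, cv_report, summaries,
                          bias_info, calibration_plots=calib)


def summarize_classes(
    height: GridRaster,
    agb: GridRaster,
    class_raster: GridRaster,
    uncertainty: unc.UncertaintyStack | None = None,
    semivariogram: unc.Semivariogram | None = None,
    class_names: dict | None = None,
    max_cells_se: int = 2000,
) -> pd.DataFrame:
    """Per-class mean, SD, standard error and area for height and AGB.

    The SE integrates per-pixel sigmas with the fitted spatial correlation
    (class-variance formula); without an uncertainty stack the classical
    SD/sqrt(m) is reported.
    """
    names = class_names or sim.CLASS_NAMES
    rows = []
    cell_ha = (height.cell_size / 100.0) ** 2
    for code in np.unique(class_raster.values[class_raster.mask]):
        sel = (class_raster.values == code) & height.mask & agb.mask
        m = int(sel.sum())
        if m == 0:
            continue
        row = {"class": names.get(int(code), str(code)), "n_cells": m,
               "area_ha": m * cell_ha}
        for label, grid in (("height", height), ("agb", agb)):
            v = grid.values[sel]
            row[f"mean_{label}"] = float(v.mean())
            row[f"sd_{label}"] = float(v.std())
        if uncertainty is not None and m >= 2:
            iy, ix = np.nonzero(sel)
            coords = np.column_stack([ix, iy]) * height.cell_size
            sig = np.nan_to_num(uncertainty.sigma_total.values[sel])
            if m > max_cells_se:
                rng = np.random.default_rng(0)
                pick = rng.choice(m, size=max_cells_se, replace=False)
                _, se = unc.class_variance(sig[pick], coords[pick], semivariogram)
            else:
                _, se = unc.class_variance(sig, coords, semivariogram)
            row["se_agb"] = se
        elif m >= 2:
            row["se_agb"] = row["sd_agb"] / np.sqrt(m)
        rows.append(row)
    return pd.DataFrame(rows)


def confusion_report(
    lulc: GridRaster, fdi_classes: GridRaster, collapse: bool = True
) -> pd.DataFrame:
    """Cross-tabulation (counts and row %) of land-cover vs FDI classes.

    With ``collapse`` the four FDI severity classes are reduced to
    intact/degraded for a 2x2 view against the land-cover intact/degraded
    split of terra firme.
    """
    lulc.require_same_grid(fdi_classes, "classification rasters")
    sel = lulc.mask & fdi_classes.mask & np.isin(lulc.values, sim.TERRA_FIRME_CODES)
    if not sel.any():
        log.warning("confusion_report: empty overlap between classifications")
        return pd.DataFrame()
    a = np.where(lulc.values[sel] == sim.CLASS_CODES["terra_firme_intact"],
                 "intact", "degraded")
    f = fdi_classes.values[sel]
    if collapse:
        b = np.where(f == 3, "intact", "degraded")
    else:
        b = np.array([dg.DEGRADATION_CLASSES[int(c)] for c in f])
    tab = pd.crosstab(pd.Series(a, name="lulc"), pd.Series(b, name="fdi"))
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"{c}_rowpct" for c in pct.columns]
    return pd.concat([tab, pct.round(2)], axis=1)
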