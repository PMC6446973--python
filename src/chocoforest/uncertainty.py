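"""Error propagation for the height and biomass maps.

Three ingredients compose the per-pixel biomass uncertainty in quadrature:

    sigma_total^2 = sigma_RS^2 + sigma_modeling^2 + sigma_field^2

* ``sigma_RS`` — the mapping (remote-sensing) error: the per-pixel standard
  deviation across bootstrap prediction maps, where whole lidar scenes (not
  cells) are the resampling unit so spatial autocorrelation cannot leak
  between training and test;
* ``sigma_modeling`` — the lidar-biomass model error, apportioned to each
  pixel in proportion to its biomass (model CV RMSE relative to the mean
  calibration biomass);
* ``sigma_field`` — field measurement and allometry error, 21.4% of pixel
  biomass.

Class-level variance integrates the pixel sigmas with the spatial
correlation function rho(d) of a fitted exponential semivariogram:

    sigma^2(class) = 1/(m(m-1)) * (sum_i sigma_i^2
                     + 2 * sum_{i<j} rho(d_ij) sigma_i sigma_j)

implemented exactly as printed (the 1/(m(m-1)) prefactor differs from the
classical 1/m^2 correlated-mean variance; a ``convention`` switch provides
the classical form for comparison). Two scene-level validation schemes are
provided: repeated leave-30%-out and leave-one-scene-out (jackknife).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from .raster import GridRaster
from .simulate import SceneFootprint, scene_cell_mask

__all__ = ["UncertaintyStack", "Semivariogram", "CVReport",
           "bootstrap_map_uncertainty", "compose_pixel_error",
           "empirical_semivariogram", "fit_semivariogram", "class_variance",
           "leave_one_scene_out"]


@dataclass
class UncertaintyStack:
    sigma_rs: GridRaster
    sigma_modeling: GridRaster
    sigma_field: GridRaster
    sigma_total: GridRaster


@dataclass
class Semivariogram:
    """Exponential semivariogram gamma(d) = c0 + c1 (1 - exp(-d/r)).

    The correlation used in class variance is rho(d) = 1 - gamma(d)/(c0+c1),
    clamped to [0, 1] and set to zero beyond the practical range (3r).
    """

    nugget: float
    partial_sill: float
    range_m: float
    degenerate: bool = False

    def gamma(self, d):
        d = np.asarray(d, float)
        return self.nugget + self.partial_sill * (1.0 - np.exp(-d / max(self.range_m, 1e-9)))

    def rho(self, d):
        d = np.asarray(d, float)
        if self.degenerate:
            return np.where(d <= 0, 1.0, 0.0)
        sill = self.nugget + self.partial_sill
        r = 1.0 - self.gamma(d) / sill if sill > 0 else np.zeros_like(d)
        r = np.clip(r, 0.0, 1.0)
        return np.where(d > 3.0 * self.range_m, 0.0, r)


@dataclass
class CVReport:
    scheme: str
    per_iteration: pd.DataFrame  # columns r2, rmse, bias (one row per iteration)
    pooled_r2: float
    pooled_rmse: float
    pooled_bias: float
    n_iterations: int
    extras: dict = field(default_factory=dict)


def _metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    resid = obs - pred
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return r2, float(np.sqrt(np.mean(resid ** 2))), float(np.mean(resid))


# ---------------------------------------------------------------------------
# Scene-resampled bootstrap of the mapping pipeline


def bootstrap_map_uncertainty(
    scenes: Sequence[SceneFootprint],
    pipeline: Callable[[Sequence[SceneFootprint]], GridRaster],
    reference: GridRaster,
    fraction: float = 0.3,
    iterations: int = 100,
    seed: int = 0,
) -> tuple[GridRaster, GridRaster, CVReport]:
    """Leave-``fraction``-of-scenes-out uncertainty of a mapping pipeline.

    ``pipeline(scene_subset)`` must return a prediction map on the reference
    grid. Per iteration the removed scenes' cells are the test set, scored
    against ``reference`` (the lidar response). Returns the mean map, the
    per-pixel SD across iterations (sigma_RS) and a CV report.
    """
    if len(scenes) < 4:
        raise ValueError("scene bootstrap needs >= 4 scenes")
    rng = np.random.default_rng(seed)
    n_out = max(1, int(round(fraction * len(scenes))))
    sum_map = np.zeros(reference.shape)
    sumsq_map = np.zeros(reference.shape)
    count_map = np.zeros(reference.shape, dtype=int)
    rows, obs_all, pred_all = [], [], []
    done = 0
    for _ in range(iterations):
        out_idx = rng.choice(len(scenes), size=n_out, replace=False)
        keep = [s for i, s in enumerate(scenes) if i not in out_idx]
        if not keep:
            continue
        try:
            pred = pipeline(keep)
        except ValueError:
            continue  # iteration with empty training: skipped
        done += 1
        ok = pred.mask
        sum_map[ok] += pred.values[ok]
        sumsq_map[ok] += pred.values[ok] ** 2
        count_map[ok] += 1
        test_mask = scene_cell_mask([scenes[i] for i in out_idx], reference)
        sel = test_mask & reference.mask & pred.mask
        if sel.sum() >= 3:
            o, p = reference.values[sel], pred.values[sel]
            r2, rmse, bias = _metrics(o, p)
            rows.append({"r2": r2, "rmse": rmse, "bias": bias})
            obs_all.append(o), pred_all.append(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count_map > 0, sum_map / np.maximum(count_map, 1), np.nan)
        var = np.clip(sumsq_map / np.maximum(count_map, 1) - mean ** 2, 0.0, None)
    sigma = np.sqrt(var)
    mask = count_map > 0
    if obs_all:
        pooled = _metrics(np.concatenate(obs_all), np.concatenate(pred_all))
    else:
        pooled = (np.nan, np.nan, np.nan)
    report = CVReport("leave30pct", pd.DataFrame(rows), *pooled, n_iterations=done)
    g = lambda v: GridRaster(v, reference.cell_size, reference.origin, mask)
    return g(mean), g(sigma), report


# ---------------------------------------------------------------------------
# Pixel error composition


def compose_pixel_error(
    sigma_rs: GridRaster,
    model,
    agb: GridRaster,
    field_rel_error: float = 0.214,
    modeling_mode: str = "relative",
) -> UncertaintyStack:
    """Compose the three error terms in quadrature at every pixel.

    The field/allometry term is ``field_rel_error`` (21.4%) of pixel AGB.
    The lidar-model term is apportioned per pixel either relative (model CV
    RMSE divided by the mean calibration AGB, times pixel AGB; default) or
    absolute (the CV RMSE everywhere).
    """
    sigma_rs.require_same_grid(agb, "sigma_RS and AGB map")
    if np.any(sigma_rs.values[sigma_rs.mask] < 0) or np.any(agb.values[agb.mask] < 0):
        raise ValueError("negative error or biomass input")
    s_field = field_rel_error * agb.values
    if modeling_mode == "relative":
        rel = model.rmse / _mean_calibration_agb(model)
        s_model = rel * agb.values
    elif modeling_mode == "absolute":
        s_model = np.full(agb.shape, float(model.rmse))
    else:
        raise ValueError("modeling_mode must be 'relative' or 'absolute'")
    s_rs = np.where(sigma_rs.mask, sigma_rs.values, 0.0)
    total = np.sqrt(s_rs ** 2 + s_model ** 2 + s_field ** 2)
    mask = agb.mask
    g = lambda v: GridRaster(np.where(mask, v, np.nan), agb.cell_size, agb.origin, mask)
    return UncertaintyStack(g(s_rs), g(s_model), g(s_field), g(total))


def _mean_calibration_agb(model) -> float:
    """Mean calibration-plot AGB implied by the fitted model; overridable."""
    mean = getattr(model, "mean_calibration_agb", None)
    if mean:
        return float(mean)
    # fall back to the model evaluated at a mid-range calibration point
    return float(model.predict(21.5, 0.6))


# ---------------------------------------------------------------------------
# Semivariogram


def empirical_semivariogram(
    grid: GridRaster, max_lag: float, n_bins: int = 15, max_cells: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical semivariance by distance bin.

    gamma(h) = mean of (z_i - z_j)^2 / 2 over pairs at distance ~ h. For
    large rasters a random subset of ``max_cells`` valid cells is used.
    """
    iy, ix = np.nonzero(grid.mask & np.isfinite(grid.values))
    if len(iy) < 100:
        raise ValueError("semivariogram needs >= 100 valid cells")
    if len(iy) > max_cells:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(iy), size=max_cells, replace=False)
        iy, ix = iy[sel], ix[sel]
    z = grid.values[iy, ix]
    xy = np.column_stack([ix, iy]) * grid.cell_size
    d = pdist(xy)
    dz2 = pdist(z[:, None], metric="sqeuclidean") / 2.0
    bins = np.linspace(0, max_lag, n_bins + 1)
    which = np.digitize(d, bins) - 1
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() < 10:
            continue
        rows.append({
            "lag": float(d[sel].mean()),
            "gamma": float(dz2[sel].mean()),
            "n_pairs": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def fit_semivariogram(
    grid: GridRaster, max_lag: float, n_bins: int = 15, **kwargs
) -> Semivariogram:
    """Fit an exponential model to the empirical semivariogram.

    A flat variogram (no resolvable spatial structure) is flagged degenerate
    and returns rho(d > 0) = 0.
    """
    emp = empirical_semivariogram(grid, max_lag, n_bins, **kwargs)
    if len(emp) < 4:
        raise ValueError("too few populated lag bins to fit a semivariogram")
    lag, gam = emp["lag"].to_numpy(), emp["gamma"].to_numpy()
    sill0 = float(gam[-3:].mean())
    model = lambda d, c0, c1, r: c0 + c1 * (1 - np.exp(-d / r))
    try:
        (c0, c1, r), _ = curve_fit(
            model, lag, gam,
            p0=(max(gam[0], 1e-6), max(sill0 - gam[0], 1e-6), max_lag / 4),
            bounds=([0, 0, 1e-6], [np.inf, np.inf, 10 * max_lag]),
            maxfev=20000,
        )
    except RuntimeError:
        return Semivariogram(float(gam.mean()), 0.0, 1e-6, degenerate=True)
    sv = Semivariogram(float(c0), float(c1), float(r))
    # flat variogram: the spatially structured part is a negligible share of
    # the sill, or the fitted range is below the grid resolution
    if c1 <= 0.05 * (c0 + c1) or r <= grid.cell_size / 10:
        sv.degenerate = True
    return sv


# ---------------------------------------------------------------------------
# Class variance with spatial correlation


def class_variance(
    sigmas: np.ndarray,
    coords: np.ndarray,
    semivariogram: Semivariogram | None = None,
    exact_limit: int = 5000,
    n_dist_bins: int = 50,
    convention: str = "printed",
) -> tuple[float, float]:
    """Variance and SE of a class mean from correlated pixel sigmas.

    Implements sigma^2(class) = 1/(m(m-1)) (sum sigma_i^2 + 2 sum_{i<j}
    rho(d_ij) sigma_i sigma_j) exactly for m <= ``exact_limit``; beyond that
    the double sum is approximated by distance-binned expectation (pairs are
    binned by distance, and rho evaluated at the bin midpoint). The
    ``classical`` convention replaces the prefactor with 1/m^2.
    """
    sigmas = np.asarray(sigmas, float)
    coords = np.asarray(coords, float)
    m = len(sigmas)
    if m < 2:
        raise ValueError("class variance needs at least 2 pixels")
    rho = semivariogram.rho if semivariogram is not None else (lambda d: np.zeros_like(np.asarray(d, float)))
    sum_sq = float(np.sum(sigmas ** 2))

    def _pair_arrays(idx):
        iu, ju = np.triu_indices(len(idx), 1)
        a, b = idx[iu], idx[ju]
        d = np.hypot(coords[a, 0] - coords[b, 0], coords[a, 1] - coords[b, 1])
        return d, sigmas[a] * sigmas[b]

    if m <= exact_limit:
        d, cross = _pair_arrays(np.arange(m))
        double = float(np.sum(rho(d) * cross))
    else:
        rng = np.random.default_rng(0)
        n_sub = exact_limit
        sel = rng.choice(m, size=n_sub, replace=False)
        d, cross = _pair_arrays(sel)
        bins = np.linspace(0, d.max() + 1e-9, n_dist_bins + 1)
        which = np.digitize(d, bins) - 1
        double_sub = 0.0
        for b in range(n_dist_bins):
            s = which == b
            if not s.any():
                continue
            double_sub += float(rho(np.array([d[s].mean()]))[0] * cross[s].sum())
        # scale pair sum from the subsample to the full population of pairs
        double = double_sub * (m * (m - 1)) / (n_sub * (n_sub - 1))
    pref = 1.0 / (m * (m - 1)) if convention == "printed" else 1.0 / (m * m)
    var = pref * (sum_sq + 2.0 * double)
    return float(var), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Leave-one-scene-out jackknife


def leave_one_scene_out(
    scenes: Sequence[SceneFootprint],
    pipeline: Callable[[Sequence[SceneFootprint]], GridRaster],
    reference: GridRaster,
    class_map: GridRaster | None = None,
    agb_of: Callable[[GridRaster], GridRaster] | None = None,
) -> CVReport:
    """Jackknife validation: one model per left-out scene.

    Per-scene R^2/RMSE/bias on the held-out cells plus pooled metrics over
    all held-out cells. When a class map is given, the report's extras carry
    a per-class comparison of mean lidar response vs independent prediction
    with percent difference.
    """
    if len(scenes) < 2:
        raise ValueError("leave-one-scene-out needs >= 2 scenes")
    rows, obs_all, pred_all, cls_all = [], [], [], []
    for i, sc in enumerate(scenes):
        keep = [s for j, s in enumerate(scenes) if j != i]
        pred = pipeline(keep)
        test = scene_cell_mask([sc], reference) & reference.mask & pred.mask
        if test.sum() < 3:
            continue
        o, p = reference.values[test], pred.values[test]
        r2, rmse, bias = _metrics(o, p)
        rows.append({"scene": i, "r2": r2, "rmse": rmse, "bias": bias,
                     "n_cells": int(test.sum())})
        obs_all.append(o), pred_all.append(p)
        if class_map is not None:
            cls_all.append(_classes_at(class_map, reference, test))
    obs = np.concatenate(obs_all)
    prd = np.concatenate(pred_all)
    pooled = _metrics(obs, prd)
    extras: dict = {}
    if class_map is not None and cls_all:
        cls = np.concatenate(cls_all)
        comp = []
        for c in np.unique(cls):
            sel = cls == c
            mo, mp = float(obs[sel].mean()), float(prd[sel].mean())
            comp.append({"class_code": int(c), "mean_lidar": mo,
                         "mean_predicted": mp, "n_cells": int(sel.sum()),
                         "pct_difference": 100.0 * abs(mp - mo) / mo if mo else np.nan})
        extras["class_comparison"] = pd.DataFrame(comp)
    df = pd.DataFrame(rows)
    extras["mean_iteration_r2"] = float(df["r2"].mean()) if len(df) else np.nan
    return CVReport("leave_one_scene_out", df, *pooled, n_iterations=len(rows),
                    extras=extras)


def _classes_at(class_map: GridRaster, grid: GridRaster, mask: np.ndarray) -> np.ndarray:
    """Class codes sampled at the centres of the masked analysis cells."""
    xs, ys = grid.cell_centers()
    iy, ix = np.nonzero(mask)
    jx = ((xs[ix] - class_map.origin[0]) / class_map.cell_size).astype(int)
    jy = ((class_map.origin[1] - ys[iy]) / class_map.cell_size).astype(int)
    jx = np.clip(jx, 0, class_map.shape[1] - 1)
    jy = np.clip(jy, 0, class_map.shape[0] - 1)
    return class_map.values[jy, jx]
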