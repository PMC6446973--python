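"""Forest Degradation Index, severity classification and biomass-loss accounting.

The degradation index of a 1-ha terra firme cell is the plain sum of its
three structure metrics,

    FDI = TCH + LCA + PC,

mean canopy height (m) plus large-tree canopy area (%) plus percent cover
(%). The mixed units are kept as printed in the source formulation (a
min-max normalisation of the components is available behind a switch,
default off). Low FDI means structurally degraded forest; three ascending
thresholds cut the index into severe / moderate-to-high / light / intact.

Biomass-loss accounting derives per-class emission factors (intact mean AGB
minus class mean AGB, Mg/ha) and the regional loss as the area-weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import GridRaster

__all__ = ["FDIResult", "compute_fdi", "calibrate_thresholds",
           "classify_degradation", "biomass_loss", "DEGRADATION_CLASSES"]

#: ascending severity order; intervals are (-inf,t1], (t1,t2], (t2,t3], (t3,inf)
DEGRADATION_CLASSES = ("severe", "moderate_to_high", "light", "intact")


@dataclass
class FDIResult:
    fdi: GridRaster
    thresholds: tuple[float, float, float] | None = None
    class_raster: GridRaster | None = None
    summary: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def compute_fdi(
    tch: GridRaster,
    lca: GridRaster,
    pc: GridRaster,
    terra_firme_mask: np.ndarray,
    normalize: bool = False,
) -> GridRaster:
    """Sum the three components over terra firme cells; nodata elsewhere."""
    tch.require_same_grid(lca, "TCH and LCA")
    tch.require_same_grid(pc, "TCH and PC")
    if terra_firme_mask.shape != tch.shape:
        raise ValueError("terra firme mask must be on the metrics grid")
    comps = [tch, lca, pc]
    arrays = []
    for c in comps:
        v = c.values.astype(float)
        if normalize:
            valid = c.mask & terra_firme_mask
            lo, hi = v[valid].min(), v[valid].max()
            v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        arrays.append(v)
    vals = arrays[0] + arrays[1] + arrays[2]
    mask = terra_firme_mask & tch.mask & lca.mask & pc.mask
    out = np.where(mask, vals, np.nan)
    return GridRaster(out, tch.cell_size, tch.origin, mask)


def calibrate_thresholds(
    fdi_values: np.ndarray,
    labels: np.ndarray | None = None,
    quantiles: tuple[float, float, float] | None = None,
) -> tuple[float, float, float]:
    """Three ascending FDI cuts, from labelled severity groups or quantiles.

    Supervised mode: ``labels`` assigns each sample an ordinal severity group
    (0 = most severe ... k = intact); cuts are midpoints between consecutive
    group medians, which must be strictly increasing. Quantile mode cuts at
    the configured percentiles of the pooled sample.
    """
    fdi_values = np.asarray(fdi_values, float)
    fdi_values = fdi_values[np.isfinite(fdi_values)]
    if quantiles is not None:
        cuts = tuple(float(np.quantile(fdi_values, q)) for q in quantiles)
    elif labels is not None:
        labels = np.asarray(labels)
        groups = np.unique(labels)
        if len(groups) < 2:
            raise ValueError("supervised calibration needs >= 2 severity groups")
        medians = [float(np.median(fdi_values[labels == g])) for g in groups]
        if any(m2 <= m1 for m1, m2 in zip(medians, medians[1:])):
            raise ValueError(
                f"group medians not strictly increasing with severity order: {medians}"
            )
        mids = [(m1 + m2) / 2 for m1, m2 in zip(medians, medians[1:])]
        while len(mids) < 3:  # fewer groups than classes: repeat the outer cut
            mids.append(mids[-1])
        cuts = tuple(mids[:3])
    else:
        raise ValueError("provide labelled samples or explicit quantiles")
    if not (cuts[0] <= cuts[1] <= cuts[2]):
        raise ValueError(f"thresholds must ascend, got {cuts}")
    return cuts


def classify_degradation(
    fdi: GridRaster,
    thresholds: tuple[float, float, float],
    height: GridRaster | None = None,
    agb: GridRaster | None = None,
) -> FDIResult:
    """Cut the FDI into four severity classes and summarise each.

    Returns the class raster (codes 0=severe .. 3=intact, -1 outside the
    mask) and a per-class table of area (ha) and mean +- SD of height and
    AGB where those maps are supplied. The four intervals partition the
    masked cells exactly.
    """
    t1, t2, t3 = thresholds
    if not t1 <= t2 <= t3:
        raise ValueError("thresholds must be ascending")
    codes = np.full(fdi.shape, -1, dtype=np.int16)
    v = fdi.values
    m = fdi.mask
    codes[m & (v <= t1)] = 0
    codes[m & (v > t1) & (v <= t2)] = 1
    codes[m & (v > t2) & (v <= t3)] = 2
    codes[m & (v > t3)] = 3
    cell_ha = (fdi.cell_size / 100.0) ** 2
    rows = []
    for code, name in enumerate(DEGRADATION_CLASSES):
        sel = codes == code
        row = {"class": name, "area_ha": float(sel.sum() * cell_ha)}
        for label, grid in (("height", height), ("agb", agb)):
            if grid is not None and sel.any():
                vals = grid.values[sel & grid.mask]
                row[f"mean_{label}"] = float(vals.mean()) if len(vals) else np.nan
                row[f"sd_{label}"] = float(vals.std()) if len(vals) else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)
    return FDIResult(
        fdi=fdi,
        thresholds=tuple(map(float, thresholds)),
        class_raster=GridRaster(codes, fdi.cell_size, fdi.origin, codes >= 0),
        summary=summary,
        metadata={"thresholds": tuple(map(float, thresholds))},
    )


def biomass_loss(class_summary: pd.DataFrame, intact_label: str = "intact") -> pd.DataFrame:
    """Emission factors and regional biomass loss from a class summary.

    For each degraded class: emission factor = intact mean AGB - class mean
    AGB (Mg/ha), percent reduction relative to intact, and loss = area x
    factor (Mg). A total row aggregates the loss over all degraded classes.
    Splitting a degraded class into subclasses with the same area-weighted
    mean leaves the total unchanged.
    """
    df = class_summary.set_index("class")
    if intact_label not in df.index:
        raise ValueError(f"summary has no {intact_label!r} class")
    intact_agb = float(df.loc[intact_label, "mean_agb"])
    rows = []
    total_loss = 0.0
    for name, row in df.iterrows():
        if name == intact_label or row.get("area_ha", 0) <= 0 or np.isnan(row.get("mean_agb", np.nan)):
            continue
        factor = intact_agb - float(row["mean_agb"])
        loss = factor * float(row["area_ha"])
        total_loss += loss
        rows.append({
            "class": name,
            "emission_factor_mg_ha": factor,
            "percent_reduction": 100.0 * factor / intact_agb,
            "area_ha": float(row["area_ha"]),
            "loss_mg": loss,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out.loc[len(out)] = {
            "class": "all_degraded",
            "emission_factor_mg_ha": total_loss / out["area_ha"].sum(),
            "percent_reduction": 100.0 * (total_loss / out["area_ha"].sum()) / intact_agb,
            "area_ha": out["area_ha"].sum(),
            "loss_mg": total_loss,
        }
    return out
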