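"""Canopy structure metrics at the 1-ha analysis grid.

Derives the three lidar structure metrics from a 1-m canopy height model
(CHM):

* **TCH** — mean top canopy height, the arithmetic mean of the 1-m pixels in
  each 100 m x 100 m cell;
* **PC** — percent vegetation cover, the share of pixels taller than 5 m;
* **LCA** — large-tree canopy area, the share of pixels belonging to
  connected crowns taller than 27 m with crown area above 100 m^2.

All thresholds are strict inequalities. Crown delineation for LCA uses
4-connected components of the >27 m mask computed across the whole raster
(components straddling cell borders are judged globally, pixels attributed
per cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import GridRaster, block_reduce_mean

__all__ = ["CanopyHeightModel", "HectareMetrics", "build_chm", "grid_tch",
           "compute_pc", "compute_lca", "hectare_metrics"]


@dataclass
class CanopyHeightModel:
    """1-m canopy height raster; negatives clamped, nodata propagated."""

    values: GridRaster
    dsm_id: str | None = None
    dtm_id: str | None = None


@dataclass
class HectareMetrics:
    tch: GridRaster  # m
    lca: GridRaster  # % of cell area
    pc: GridRaster  # % of cell area
    valid_fraction: GridRaster


def build_chm(dsm: GridRaster, dtm: GridRaster) -> CanopyHeightModel:
    """CHM = DSM - DTM, clamped at zero; nodata where either input is nodata."""
    dsm.require_same_grid(dtm, "DSM and DTM")
    vals = np.clip(dsm.values - dtm.values, 0.0, None)
    mask = dsm.mask & dtm.mask
    return CanopyHeightModel(GridRaster(vals, dsm.cell_size, dsm.origin, mask))


def _factor(chm: GridRaster, cell: float) -> int:
    f = cell / chm.cell_size
    if abs(f - round(f)) > 1e-9:
        raise ValueError(f"analysis cell {cell} m is not a multiple of CHM cell {chm.cell_size} m")
    return int(round(f))


def grid_tch(chm: CanopyHeightModel | GridRaster, cell: float = 100.0,
             min_valid_fraction: float = 0.5) -> tuple[GridRaster, GridRaster]:
    """Mean top canopy height per analysis cell, with its valid fraction.

    Cells whose valid-pixel fraction falls below ``min_valid_fraction``
    (default 0.5) are set to nodata.
    """
    grid = chm.values if isinstance(chm, CanopyHeightModel) else chm
    return block_reduce_mean(grid, _factor(grid, cell), min_valid_fraction)


def compute_pc(chm: CanopyHeightModel | GridRaster, cell: float = 100.0,
               height_threshold: float = 5.0) -> GridRaster:
    """Percent vegetation cover: 100 x fraction of valid pixels above 5 m (strict)."""
    grid = chm.values if isinstance(chm, CanopyHeightModel) else chm
    f = _factor(grid, cell)
    tall = (grid.values > height_threshold) & grid.mask
    agg, _ = block_reduce_mean(
        GridRaster(tall.astype(float), grid.cell_size, grid.origin, grid.mask), f
    )
    return GridRaster(agg.values * 100.0, agg.cell_size, agg.origin, agg.mask)


def compute_lca(chm: CanopyHeightModel | GridRaster, cell: float = 100.0,
                height_threshold: float = 27.0, min_crown_area: float = 100.0) -> GridRaster:
    """Percent of cell area under large-tree crowns.

    Pixels above 27 m are grouped into 4-connected components over the whole
    raster; pixels in components of area strictly greater than 100 m^2 count
    toward LCA = 100 x counted-pixel fraction per cell.
    """
    grid = chm.values if isinstance(chm, CanopyHeightModel) else chm
    f = _factor(grid, cell)
    tall = (grid.values > height_threshold) & grid.mask
    labels, n = ndimage.label(tall, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    counted = np.zeros(grid.shape, dtype=bool)
    if n:
        sizes = np.bincount(labels.ravel())
        pixel_area = grid.cell_size ** 2
        big = sizes * pixel_area > min_crown_area
        big[0] = False
        counted = big[labels]
    agg, _ = block_reduce_mean(
        GridRaster(counted.astype(float), grid.cell_size, grid.origin, grid.mask), f
    )
    return GridRaster(agg.values * 100.0, agg.cell_size, agg.origin, agg.mask)


def hectare_metrics(chm: CanopyHeightModel | GridRaster, cell: float = 100.0,
                    min_valid_fraction: float = 0.5) -> HectareMetrics:
    """All three metrics plus the per-cell valid fraction."""
    tch, frac = grid_tch(chm, cell, min_valid_fraction)
    return HectareMetrics(
        tch=tch,
        lca=compute_lca(chm, cell),
        pc=compute_pc(chm, cell),
        valid_fraction=frac,
    )
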