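"""Gridded raster container used throughout the pipeline.

A :class:`GridRaster` is a 2-D field with a square cell size in metres, a
top-left origin in projected coordinates, and an explicit nodata mask.  It is
the carrier for every map in the pipeline: 1-m canopy height models, 100-m
canopy metrics, biomass, degradation index and uncertainty surfaces, and the
30-m land-cover raster.

Conventions: row-major storage, row 0 at the top (northernmost); cell (i, j)
covers ``x in [origin_x + j*cell, origin_x + (j+1)*cell)`` and
``y in (origin_y - (i+1)*cell, origin_y - i*cell]``.  All analysis grids are
cell-centred and the 1-ha grid is aligned to 100-m multiples of the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridRaster", "block_reduce_mean", "read_ascii_grid"]


@dataclass
class GridRaster:
    """A single-band gridded field with georeferencing metadata.

    Parameters
    ----------
    values
        2-D float or integer array. Nodata cells may hold any value; validity
        is tracked by :attr:`mask`.
    cell_size
        Edge length of a (square) cell in metres.
    origin
        ``(x, y)`` of the raster's top-left corner in metres.
    mask
        Boolean array, ``True`` where the cell holds valid data. Defaults to
        all-valid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GridRaster values must be 2-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in metres."""
        ny, nx = self.shape
        x0, y0 = self.origin
        return (x0, x0 + nx * self.cell_size, y0 - ny * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y coordinates of cell centres (1-D each)."""
        ny, nx = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 - (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def same_grid(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def require_same_grid(self, other: "GridRaster", what: str = "rasters") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch between {what}: "
                f"{self.shape}@{self.cell_size}m/{self.origin} vs "
                f"{other.shape}@{other.cell_size}m/{other.origin}"
            )

    def copy(self) -> "GridRaster":
        return GridRaster(self.values.copy(), self.cell_size, self.origin, self.mask.copy())

    def filled(self, fill_value: float = np.nan) -> np.ndarray:
        """Values with nodata cells replaced by ``fill_value``."""
        return np.where(self.mask, self.values, fill_value)

    # -- I/O -------------------------------------------------------------
    def to_ascii(self, path: str | Path, nodata: float = -9999.0, fmt: str = "%.6g") -> None:
        """Write as an ESRI ASCII grid (plain text, widely readable)."""
        ny, nx = self.shape
        x0, y0 = self.origin
        out = np.where(self.mask, self.values, nodata)
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0 - ny * self.cell_size}\n"
            f"cellsize {self.cell_size}\nNODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt=fmt)

    def to_tiff(self, path: str | Path) -> None:
        """Export as a single-band TIFF (nodata encoded as NaN)."""
        import tifffile

        out = np.where(self.mask, self.values, np.nan).astype(np.float32)
        tifffile.imwrite(str(path), out)


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid written by :meth:`GridRaster.to_ascii`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    cell = header["cellsize"]
    ny = int(header["nrows"])
    origin = (header["xllcorner"], header["yllcorner"] + ny * cell)
    nodata = header.get("nodata_value", -9999.0)
    mask = values != nodata
    return GridRaster(values, cell, origin, mask)


def block_reduce_mean(
    raster: GridRaster, factor: int, min_valid_fraction: float = 0.0
) -> tuple[GridRaster, GridRaster]:
    """Aggregate a raster by an integer factor using the mean of valid cells.

    Returns the aggregated raster and a companion raster holding the valid
    fraction per block. Blocks whose valid fraction falls below
    ``min_valid_fraction`` are set to nodata.
    """
    ny, nx = raster.shape
    if ny % factor or nx % factor:
        raise ValueError(f"raster shape {raster.shape} not divisible by factor {factor}")
    by, bx = ny // factor, nx // factor
    vals = np.where(raster.mask, raster.values, 0.0).reshape(by, factor, bx, factor)
    valid = raster.mask.reshape(by, factor, bx, factor)
    counts = valid.sum(axis=(1, 3))
    sums = vals.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    frac = counts / float(factor * factor)
    mask = frac >= max(min_valid_fraction, np.finfo(float).tiny)
    agg = GridRaster(means, raster.cell_size * factor, raster.origin, mask)
    return agg, GridRaster(frac, raster.cell_size * factor, raster.origin)
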