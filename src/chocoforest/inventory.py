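"""Field-inventory processing: wood density, plot biomass, lidar colocation.

Turns tree lists into plot-level mean wood density and aboveground biomass
(Mg/ha) and co-locates plots with the 1-ha lidar grid for calibrating the
height-biomass model. Wood density is assigned per stem from a taxonomic
lookup table in the order species -> genus -> family; stems that match at no
rank receive the mean wood density of the matched stems in their plot, and a
plot with no matches at all falls back to its forest-class mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridRaster
from .simulate import PlotRecord, TreeRecord

__all__ = [
    "WoodDensityTable",
    "assign_wood_density",
    "plot_agb",
    "aggregate_quarter_plots",
    "colocate_with_lidar",
    "class_mean_wd",
]

_RANKS = ("species", "genus", "family")


@dataclass
class WoodDensityTable:
    """Taxon -> wood density lookup with per-rank indices."""

    rows: list[tuple[str, str, float]]  # (name, rank, wd g/cm3)

    def __post_init__(self) -> None:
        self._index: dict[str, dict[str, float]] = {r: {} for r in _RANKS}
        seen = set()
        for name, rank, wd in self.rows:
            if rank not in _RANKS:
                raise ValueError(f"unknown rank {rank!r}")
            if (name, rank) in seen:
                raise ValueError(f"duplicate wood-density key ({name}, {rank})")
            seen.add((name, rank))
            self._index[rank][name] = float(wd)

    def lookup(self, rank: str, name: str | None) -> float | None:
        if name is None:
            return None
        return self._index[rank].get(name)

    @classmethod
    def from_csv(cls, path) -> "WoodDensityTable":
        df = pd.read_csv(path)
        return cls(list(df[["taxon", "rank", "wd"]].itertuples(index=False, name=None)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.rows, columns=["taxon", "rank", "wd"]).to_csv(path, index=False)


def assign_wood_density(
    trees: list[TreeRecord],
    table: WoodDensityTable,
    class_means: dict[str, float] | None = None,
    plot_classes: dict[str, str] | None = None,
) -> Counter:
    """Assign wood density to every tree; return a tally of assignment levels.

    Lookup order is species, then genus, then family. Unmatched trees get the
    mean wood density of the matched trees in their plot (level
    ``plot_mean``); a plot with zero matched trees gets its class mean
    (level ``class_mean``) when ``class_means`` and ``plot_classes`` are
    given, otherwise an error naming the plot is raised.

    The assignment is idempotent and independent of tree order within a plot:
    the plot mean is computed over directly-matched trees only.
    """
    if not table.rows:
        raise ValueError("wood-density table is empty")
    tally: Counter = Counter()
    by_plot: dict[str, list[TreeRecord]] = {}
    for t in trees:
        by_plot.setdefault(t.plot_id, []).append(t)

    for pid, plot_trees in by_plot.items():
        unmatched = []
        matched_wds = []
        for t in plot_trees:
            for rank, name in (
                ("species", t.species),
                ("genus", t.genus),
                ("family", t.family),
            ):
                wd = table.lookup(rank, name)
                if wd is not None:
                    t.wd, t.wd_level = wd, rank
                    tally[rank] += 1
                    matched_wds.append(wd)
                    break
            else:
                unmatched.append(t)
        if unmatched:
            if matched_wds:
                fill, level = float(np.mean(matched_wds)), "plot_mean"
            else:
                cls = (plot_classes or {}).get(pid)
                if class_means is None or cls is None or cls not in class_means:
                    raise ValueError(
                        f"plot {pid!r} has no taxonomically matched trees and no "
                        "class-mean wood density to fall back on"
                    )
                fill, level = class_means[cls], "class_mean"
            for t in unmatched:
                t.wd, t.wd_level = fill, level
                tally[level] += 1
    return tally


def plot_agb(plot: PlotRecord, trees: list[TreeRecord], allometry=None) -> float:
    """Plot aboveground biomass in Mg/ha from per-stem biomass.

    ``allometry(tree) -> kg`` computes stem biomass; by default the stem's
    pre-computed ``biomass_kg`` is used (the generator's stand-in allometry).
    Stem masses are summed and divided by the plot area in hectares.
    """
    if plot.side not in (50.0, 100.0):
        raise ValueError(f"unknown plot side {plot.side} for plot {plot.plot_id}")
    if not trees:
        return 0.0
    if allometry is None:
        masses = [t.biomass_kg for t in trees]
        if any(m is None for m in masses):
            raise ValueError("trees carry no stem biomass and no allometry was given")
    else:
        masses = [allometry(t) for t in trees]
    area_ha = (plot.side / 100.0) ** 2
    return float(np.sum(masses)) / 1000.0 / area_ha


def aggregate_quarter_plots(
    plots: list[PlotRecord], require_in_scene: "callable | None" = None
) -> tuple[list[PlotRecord], list[str]]:
    """Aggregate complete 0.25-ha plots four-by-four into synthetic 1-ha plots.

    Uses the nearest-four partner sets recorded at generation time. A partner
    set is aggregated only if all four members are present, not flagged
    missing, and (optionally) inside a lidar scene; incomplete sets are
    excluded from calibration but their members remain available for
    wood-density statistics. Aggregated AGB and mean WD are area-weighted
    means (equal areas here, so plain means).

    Returns the aggregated plots and the ids of excluded clusters.
    """
    by_id = {p.plot_id: p for p in plots}
    seen: set[tuple[str, ...]] = set()
    out: list[PlotRecord] = []
    excluded: list[str] = []
    for p in plots:
        if p.side != 50.0 or p.missing or not p.partner_set:
            continue
        key = p.partner_set
        if key in seen:
            continue
        seen.add(key)
        members = [by_id.get(pid) for pid in key]
        ok = all(
            m is not None and not m.missing and m.agb is not None for m in members
        )
        if ok and require_in_scene is not None:
            ok = all(require_in_scene(m) for m in members)
        if not ok or len(members) != 4:
            excluded.append("+".join(key))
            continue
        cx = float(np.mean([m.center[0] for m in members]))
        cy = float(np.mean([m.center[1] for m in members]))
        agg = PlotRecord(
            plot_id="AGG-" + "+".join(key),
            center=(cx, cy),
            side=100.0,
            cluster_id=members[0].cluster_id,
            forest_class=members[0].forest_class,
            agb=float(np.mean([m.agb for m in members])),
            mean_wd=float(np.mean([m.mean_wd for m in members])),
        )
        if all(m.tch_true is not None for m in members):
            agg.tch_true = float(np.mean([m.tch_true for m in members]))
        if all(m.tch_lidar is not None for m in members):
            # equal member areas: the aggregate TCH is the plain member mean
            agg.tch_lidar = float(np.mean([m.tch_lidar for m in members]))
        out.append(agg)
    return out, excluded


def colocate_with_lidar(
    plots: list[PlotRecord], chm: GridRaster, min_coverage: float = 0.9
) -> list[PlotRecord]:
    """Fill ``tch_lidar`` with the mean of 1-m CHM pixels inside each plot.

    Plots with less than ``min_coverage`` valid-CHM coverage are flagged;
    plots with no overlap at all are dropped.
    """
    kept: list[PlotRecord] = []
    x0, y0 = chm.origin
    ny, nx = chm.shape
    for p in plots:
        if p.missing:
            continue
        half = p.side / 2.0
        jx0 = int(np.floor(p.center[0] - half - x0))
        jx1 = int(np.ceil(p.center[0] + half - x0))
        iy0 = int(np.floor(y0 - (p.center[1] + half)))
        iy1 = int(np.ceil(y0 - (p.center[1] - half)))
        jx0c, jx1c = max(jx0, 0), min(jx1, nx)
        iy0c, iy1c = max(iy0, 0), min(iy1, ny)
        if jx0c >= jx1c or iy0c >= iy1c:
            continue  # no overlap: dropped
        window_vals = chm.values[iy0c:iy1c, jx0c:jx1c]
        window_mask = chm.mask[iy0c:iy1c, jx0c:jx1c]
        n_valid = int(window_mask.sum())
        n_expected = (jx1 - jx0) * (iy1 - iy0)
        if n_valid == 0:
            continue
        p.tch_lidar = float(window_vals[window_mask].mean())
        p.coverage_flag = n_valid / n_expected < min_coverage
        kept.append(p)
    return kept


def class_mean_wd(trees: list[TreeRecord], plot_classes: dict[str, str]) -> dict[str, float]:
    """Unweighted per-tree mean wood density for each forest class.

    Classes with zero trees are omitted. The result is used to paint the
    wood-density map over the land-cover raster.
    """
    acc: dict[str, list[float]] = {}
    for t in trees:
        if t.wd is None:
            raise ValueError("assign wood density before computing class means")
        cls = plot_classes.get(t.plot_id)
        if cls is None:
            continue
        acc.setdefault(cls, []).append(t.wd)
    return {c: float(np.mean(v)) for c, v in acc.items()}
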