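"""Inventory processing: wood-density assignment, plot AGB, aggregation, colocation."""

import numpy as np
import pytest

from chocoforest.inventory import (
    WoodDensityTable,
    aggregate_quarter_plots,
    assign_wood_density,
    class_mean_wd,
    colocate_with_lidar,
    plot_agb,
)
from chocoforest.raster import GridRaster
from chocoforest.simulate import ClusterDesign, PlotRecord, TreeRecord, simulate_plots
from chocoforest.taxa import SyntheticTaxonomy


def _tree(pid="P1", sp=None, ge=None, fa=None, dbh=20.0):
    return TreeRecord(pid, 0.0, 0.0, dbh, sp, ge, fa)


TABLE = WoodDensityTable([
    ("cecropia_x", "species", 0.79),
    ("cecropia", "genus", 0.45),
    ("urticaceae", "family", 0.50),
])


class TestWoodDensity:
    def test_lookup_order_species_first(self):
        t = _tree(sp="cecropia_x", ge="cecropia", fa="urticaceae")
        tally = assign_wood_density([t], TABLE)
        assert (t.wd, t.wd_level) == (0.79, "species")
        assert tally == {"species": 1}

    def test_genus_then_family_fallback(self):
        t1 = _tree(sp="unknown_sp", ge="cecropia")
        t2 = _tree(sp=None, ge="novel", fa="urticaceae")
        assign_wood_density([t1, t2], TABLE)
        assert (t1.wd, t1.wd_level) == (0.45, "genus")
        assert (t2.wd, t2.wd_level) == (0.50, "family")

    def test_unmatched_gets_plot_mean(self):
        trees = [_tree(sp="cecropia_x"), _tree(ge="cecropia"), _tree()]
        tally = assign_wood_density(trees, TABLE)
        assert trees[2].wd == pytest.approx((0.79 + 0.45) / 2)
        assert trees[2].wd_level == "plot_mean"
        assert tally["plot_mean"] == 1

    def test_fully_unmatched_plot_uses_class_mean_or_raises(self):
        trees = [_tree(), _tree()]
        with pytest.raises(ValueError, match="P1"):
            assign_wood_density(trees, TABLE)
        tally = assign_wood_density(
            trees, TABLE, class_means={"wetland": 0.49}, plot_classes={"P1": "wetland"}
        )
        assert all(t.wd == 0.49 for t in trees)
        assert tally["class_mean"] == 2

    def test_assignment_is_order_independent(self):
        a = [_tree(sp="cecropia_x"), _tree(), _tree(ge="cecropia")]
        b = [a[1], a[2], a[0]]
        assign_wood_density(b, TABLE)
        wd_rev = [t.wd for t in a]
        for t in a:
            t.wd = t.wd_level = None
        assign_wood_density(a, TABLE)
        assert [t.wd for t in a] == wd_rev

    def test_duplicate_table_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            WoodDensityTable([("x", "genus", 0.5), ("x", "genus", 0.6)])

    def test_identification_mix_tally(self, small_truth, small_scenes):
        design = ClusterDesign(id_mix=(0.12, 0.54, 0.24, 0.10), stems_per_ha=1500.0)
        taxonomy = SyntheticTaxonomy()
        plots, trees = simulate_plots(small_truth, small_scenes, design, seed=9,
                                      n_clusters=2, taxonomy=taxonomy)
        classes = {p.plot_id: p.forest_class for p in plots}
        means = {c: SyntheticTaxonomy.class_mean_wd(c) for c in classes.values()}
        tally = assign_wood_density(trees, WoodDensityTable(taxonomy.wood_density_rows()),
                                    means, classes)
        n = len(trees)
        assert abs(tally["species"] / n - 0.12) < 0.02
        assert abs(tally["genus"] / n - 0.54) < 0.02
        assert abs(tally["family"] / n - 0.24) < 0.02
        assert abs((tally["plot_mean"] + tally.get("class_mean", 0)) / n - 0.10) < 0.02


class TestPlotAGB:
    def test_empty_plot_is_zero(self):
        assert plot_agb(PlotRecord("p", (0, 0), 100.0, "c", "tf"), []) == 0.0

    def test_unit_conversion_quarter_hectare(self):
        p = PlotRecord("p", (0, 0), 50.0, "c", "tf")
        t = _tree(); t.biomass_kg = 500.0
        assert plot_agb(p, [t]) == pytest.approx(2.0)

    def test_linearity_in_stem_biomass(self):
        p = PlotRecord("p", (0, 0), 100.0, "c", "tf")
        trees = [_tree() for _ in range(5)]
        for i, t in enumerate(trees):
            t.biomass_kg = 100.0 * (i + 1)
        base = plot_agb(p, trees)
        for t in trees:
            t.biomass_kg *= 2
        assert plot_agb(p, trees) == pytest.approx(2 * base)

    def test_unknown_plot_side_raises(self):
        with pytest.raises(ValueError, match="side"):
            plot_agb(PlotRecord("p", (0, 0), 70.0, "c", "tf"), [])


class TestAggregation:
    def _sats(self, n, agb=None):
        out = []
        for i in range(n):
            p = PlotRecord(f"S{i}", (float(250 * i), 0.0), 50.0, "C", "tf",
                           agb=(agb[i] if agb else 100.0), mean_wd=0.6)
            out.append(p)
        ids = tuple(sorted(p.plot_id for p in out[:4]))
        for p in out[:4]:
            p.partner_set = ids
        return out

    def test_mean_of_equal_areas(self):
        sats = self._sats(4, agb=[100, 200, 300, 400])
        agg, excluded = aggregate_quarter_plots(sats)
        assert len(agg) == 1 and not excluded
        assert agg[0].agb == pytest.approx(250.0)
        assert agg[0].side == 100.0

    def test_incomplete_cluster_excluded(self):
        sats = self._sats(4)
        sats[1].missing = True
        agg, excluded = aggregate_quarter_plots(sats)
        assert agg == [] and len(excluded) == 1

    def test_eight_members_give_two_aggregates(self, small_truth, small_scenes):
        plots, _ = simulate_plots(small_truth, small_scenes,
                                  ClusterDesign(noise_cv=0.0), seed=31, n_clusters=2)
        sats = [p for p in plots if p.side == 50.0 and not p.missing]
        agg, _ = aggregate_quarter_plots(plots)
        # every aggregate is the mean of its recorded partner set
        by_id = {p.plot_id: p for p in plots}
        for a in agg:
            members = a.plot_id.replace("AGG-", "").split("+")
            assert a.agb == pytest.approx(np.mean([by_id[m].agb for m in members]))

    def test_aggregate_conserves_area_weighted_agb(self):
        sats = self._sats(4, agb=[120, 80, 240, 160])
        agg, _ = aggregate_quarter_plots(sats)
        assert agg[0].agb == pytest.approx(np.mean([120, 80, 240, 160]))


class TestColocation:
    def test_constant_chm(self):
        chm = GridRaster(np.full((200, 200), 21.8), 1.0, (0.0, 200.0))
        p = PlotRecord("p", (100.0, 100.0), 100.0, "c", "tf")
        kept = colocate_with_lidar([p], chm)
        assert kept[0].tch_lidar == pytest.approx(21.8)
        assert not kept[0].coverage_flag

    def test_partial_overlap_flagged(self):
        chm = GridRaster(np.full((200, 200), 10.0), 1.0, (0.0, 200.0))
        p = PlotRecord("p", (0.0, 100.0), 100.0, "c", "tf")  # half outside
        kept = colocate_with_lidar([p], chm)
        assert kept[0].coverage_flag

    def test_no_overlap_dropped(self):
        chm = GridRaster(np.full((100, 100), 10.0), 1.0, (0.0, 100.0))
        p = PlotRecord("p", (1000.0, 1000.0), 100.0, "c", "tf")
        assert colocate_with_lidar([p], chm) == []

    def test_matches_brute_force_polygon_mean(self, rng):
        z = rng.uniform(0, 40, (300, 300))
        chm = GridRaster(z, 1.0, (0.0, 300.0))
        p = PlotRecord("p", (150.0, 150.0), 100.0, "c", "tf")
        kept = colocate_with_lidar([p], chm)
        assert kept[0].tch_lidar == pytest.approx(z[100:200, 100:200].mean(), abs=1e-9)


class TestClassMeanWD:
    def test_hand_cases(self):
        trees = [_tree("A"), _tree("A"), _tree("B")]
        trees[0].wd, trees[1].wd, trees[2].wd = 0.4, 0.8, 0.6
        means = class_mean_wd(trees, {"A": "terra_firme", "B": "wetland"})
        assert means["terra_firme"] == pytest.approx(0.6)
        assert means["wetland"] == pytest.approx(0.6)

    def test_recovers_simulated_class_means(self, small_truth, small_scenes):
        taxonomy = SyntheticTaxonomy()
        plots, trees = simulate_plots(small_truth, small_scenes,
                                      ClusterDesign(stems_per_ha=1500.0), seed=13,
                                      n_clusters=2, taxonomy=taxonomy)
        classes = {p.plot_id: p.forest_class for p in plots}
        cmeans = {c: SyntheticTaxonomy.class_mean_wd(c) for c in classes.values()}
        assign_wood_density(trees, WoodDensityTable(taxonomy.wood_density_rows()),
                            cmeans, classes)
        got = class_mean_wd(trees, classes)
        for cls, mean in got.items():
            expect = SyntheticTaxonomy.class_mean_wd(cls)
            n = sum(1 for t in trees if classes[t.plot_id] == cls)
            se = 0.05 / np.sqrt(n)  # species-level spread of the synthetic flora
            assert abs(mean - expect) < max(2 * se, 0.02)
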