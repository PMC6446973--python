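"""Synthetic-landscape generator: determinism, class structure, plots, predictors."""

import numpy as np
import pytest

from chocoforest.raster import GridRaster
from chocoforest.simulate import (
    CLASS_CODES,
    ClusterDesign,
    SceneFootprint,
    SimulationConfig,
    correlated_field,
    sample_scenes,
    simulate_landscape,
    simulate_plots,
    simulate_predictors,
)


class TestLandscape:
    def test_fixed_seed_is_bit_identical(self, small_truth):
        again = simulate_landscape(SimulationConfig(size=(1500.0, 1500.0), seed=7))
        assert np.array_equal(small_truth.height_true.values, again.height_true.values)
        assert np.array_equal(small_truth.class_map.values, again.class_map.values)
        assert np.array_equal(
            small_truth.degradation_severity.values, again.degradation_severity.values
        )

    def test_zero_variance_yields_constant_class_height(self):
        cfg = SimulationConfig(size=(900.0, 900.0), seed=1, degraded_fraction=0.0)
        cfg.terra_firme.sd_height = 0.0
        truth = simulate_landscape(cfg)
        tf30 = truth.class_map.values == CLASS_CODES["terra_firme_intact"]
        # expand the 30-m class mask to the 1-m grid
        tf1 = np.kron(tf30, np.ones((30, 30), dtype=bool))
        h = truth.height_true.values[: tf1.shape[0], : tf1.shape[1]][tf1]
        assert np.allclose(h, 21.8)

    def test_forest_class_fractions_match_configuration(self):
        cfg = SimulationConfig(size=(4500.0, 4500.0), seed=2)
        truth = simulate_landscape(cfg)
        v = truth.class_map.values
        forest = v > 0
        tf = np.isin(v, (1, 2)).sum() / forest.sum()
        wet = (v == 3).sum() / forest.sum()
        man = (v == 4).sum() / forest.sum()
        assert abs(tf - 0.908) < 0.02
        assert abs(wet - 0.078) < 0.02
        assert abs(man - 0.014) < 0.02

    def test_wd_map_follows_class_map(self, small_truth):
        cfg = small_truth.config
        v = small_truth.class_map.values
        wd = small_truth.wd_map.values
        for codes, expect in (((1, 2), cfg.terra_firme.wood_density),
                              ((3,), cfg.wetland.wood_density),
                              ((4,), cfg.mangrove.wood_density)):
            sel = np.isin(v, codes)
            assert np.allclose(wd[sel], expect)

    def test_severity_zero_on_intact_and_heights_nonnegative(self, small_truth):
        sev = small_truth.degradation_severity.values
        intact = small_truth.class_map.values == CLASS_CODES["terra_firme_intact"]
        assert np.all(sev[intact] == 0.0)
        assert np.all(small_truth.height_true.values >= 0.0)

    def test_degradation_lowers_class_mean_height(self, small_truth):
        v = small_truth.class_map.values
        h30 = _block_mean(small_truth.height_true.values, 30)
        assert h30[v == 2].mean() < h30[v == 1].mean()

    def test_region_too_small_raises(self):
        with pytest.raises(ValueError, match="1-ha"):
            SimulationConfig(size=(50.0, 50.0)).validate()

    def test_class_mean_height_converges_with_region_size(self):
        cfg = SimulationConfig(size=(3000.0, 3000.0), seed=9, degraded_fraction=0.0)
        truth = simulate_landscape(cfg)
        tf30 = truth.class_map.values == CLASS_CODES["terra_firme_intact"]
        h30 = _block_mean(truth.height_true.values, 30)
        vals = h30[tf30]
        se = vals.std() / np.sqrt(len(vals))
        # correlated field: effective n is much smaller than the cell count
        assert abs(vals.mean() - 21.8) < max(2 * se, 0.5)


def _block_mean(a, f):
    ny, nx = a.shape[0] // f, a.shape[1] // f
    return a[: ny * f, : nx * f].reshape(ny, f, nx, f).mean(axis=(1, 3))


class TestCorrelatedField:
    def test_standardised(self, rng):
        f = correlated_field((120, 120), 10.0, 100.0, rng)
        assert abs(f.mean()) < 1e-9
        assert abs(f.std() - 1.0) < 1e-9

    def test_longer_range_means_smoother_field(self):
        r1 = correlated_field((150, 150), 10.0, 20.0, np.random.default_rng(1))
        r2 = correlated_field((150, 150), 10.0, 200.0, np.random.default_rng(1))
        # lag-1 autocorrelation grows with the range
        ac = lambda f: np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert ac(r2) > ac(r1)


class TestPredictors:
    def test_noiseless_bands_are_deterministic_functions_of_height(self, small_truth):
        cfg = SimulationConfig(size=(1500.0, 1500.0), seed=7, noise_level=0.0)
        b1 = simulate_predictors(small_truth, cfg)
        b2 = simulate_predictors(small_truth, cfg)
        for x, y in zip(b1, b2):
            assert np.array_equal(x.values, y.values)

    def test_hv_band_saturates_above_threshold(self):
        cfg = SimulationConfig(size=(600.0, 600.0), seed=3, noise_level=0.0,
                               degraded_fraction=0.0)
        cfg.terra_firme.sd_height = 0.0
        truth = simulate_landscape(cfg)
        # plant two supra-saturation heights directly
        truth.height_true.values[:30, :30] = 28.0
        truth.height_true.values[30:60, :30] = 35.0
        bands = simulate_predictors(truth, cfg)
        hv = bands[5].values
        assert hv[0, 0] == hv[1, 0]  # both saturated at 25 m

    def test_hv_correlation_with_height_drops_past_saturation(self, small_truth):
        cfg = SimulationConfig(size=(1500.0, 1500.0), seed=7)
        bands = simulate_predictors(small_truth, cfg)
        h = _block_mean(small_truth.height_true.values, 30)
        hv = bands[5].values
        below, above = h < 25.0, h >= 25.0
        r_below = np.corrcoef(h[below], hv[below])[0, 1]
        r_above = np.corrcoef(h[above], hv[above])[0, 1]
        assert r_below > r_above

    def test_radar_gaps_masked(self, small_truth):
        cfg = SimulationConfig(size=(1500.0, 1500.0), seed=7, radar_gap_fraction=0.2)
        bands = simulate_predictors(small_truth, cfg)
        assert not bands[5].mask.all()
        assert bands[0].mask.all()  # optical bands unaffected


class TestScenes:
    def test_footprint_contract(self):
        with pytest.raises(ValueError):
            SceneFootprint((0, 0), 1000.0, 5000.0, 30.0)
        with pytest.raises(ValueError):
            SceneFootprint((0, 0), 900.0, 5000.0, 45.0)
        with pytest.raises(ValueError):
            SceneFootprint((0, 0), 1000.0, 7000.0, 45.0)
        sc = SceneFootprint((0, 0), 1000.0, 10000.0, 315.0)
        assert sc.area_ha == 1000.0

    def test_zero_scenes_and_determinism(self, small_truth):
        assert sample_scenes(small_truth, 0, seed=1) == []
        a = sample_scenes(small_truth, 2, seed=4, lengths=(5000.0,))
        b = sample_scenes(small_truth, 2, seed=4, lengths=(5000.0,))
        assert a == b

    def test_headings_are_multiples_of_45(self, small_truth):
        scenes = sample_scenes(small_truth, 2, seed=5, lengths=(5000.0,))
        assert all(s.heading % 45 == 0 for s in scenes)
        assert all(s.area_ha in (500.0, 1000.0, 2000.0) for s in scenes)

    def test_too_many_scenes_raises(self, small_truth):
        with pytest.raises(RuntimeError, match="non-overlapping"):
            sample_scenes(small_truth, 40, seed=1, lengths=(20000.0,),
                          max_attempts=300)


class TestPlots:
    def test_cluster_geometry_and_missing_flags(self, small_inventory):
        plots, _ = small_inventory
        clusters = {p.cluster_id for p in plots}
        for cid in clusters:
            members = [p for p in plots if p.cluster_id == cid]
            perm = [p for p in members if p.side == 100.0]
            sats = [p for p in members if p.side == 50.0]
            assert len(perm) == 1 and len(sats) == 8
            px, py = perm[0].center
            for s in sats:
                d = np.hypot(s.center[0] - px, s.center[1] - py)
                assert d in (250.0, 500.0)

    def test_noiseless_plot_agb_matches_stand_in_allometry(self, small_truth, small_scenes):
        design = ClusterDesign(noise_cv=0.0, a_true=17.8, b_true=1.0)
        plots, _ = simulate_plots(small_truth, small_scenes, design, seed=5,
                                  n_clusters=1)
        for p in plots:
            if p.missing:
                continue
            assert p.agb == pytest.approx(17.8 * p.tch_true * p.mean_wd, rel=1e-12)

    def test_all_species_mix_resolves_every_tree(self, small_truth, small_scenes):
        design = ClusterDesign(id_mix=(1.0, 0.0, 0.0, 0.0))
        _, trees = simulate_plots(small_truth, small_scenes, design, seed=6,
                                  n_clusters=1)
        assert all(t.species is not None for t in trees)

    def test_fixed_seed_reproduces_trees(self, small_truth, small_scenes):
        a = simulate_plots(small_truth, small_scenes, ClusterDesign(), seed=8, n_clusters=1)
        b = simulate_plots(small_truth, small_scenes, ClusterDesign(), seed=8, n_clusters=1)
        assert [(t.plot_id, t.dbh_cm, t.biomass_kg) for t in a[1]] == [
            (t.plot_id, t.dbh_cm, t.biomass_kg) for t in b[1]
        ]
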