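"""Error composition, semivariogram, class variance and scene-level validation."""

import numpy as np
import pytest

from chocoforest.agb_model import AGBModel
from chocoforest.raster import GridRaster
from chocoforest.simulate import SceneFootprint, correlated_field, scene_cell_mask
from chocoforest.uncertainty import (
    Semivariogram,
    bootstrap_map_uncertainty,
    class_variance,
    compose_pixel_error,
    empirical_semivariogram,
    fit_semivariogram,
    leave_one_scene_out,
)


def _g(values, cell=100.0):
    v = np.asarray(values, float)
    return GridRaster(v, cell, (0.0, v.shape[0] * cell))


class TestComposePixelError:
    def _model(self):
        m = AGBModel(17.8, 1.0, r2=0.72, rmse=31.6, bias=0.11)
        m.mean_calibration_agb = 200.0
        return m

    def test_three_four_five_quadrature(self):
        m = self._model()
        agb = _g([[100.0]])
        sig = compose_pixel_error(_g([[30.0]]), m, agb, field_rel_error=0.0,
                                  modeling_mode="absolute")
        # override the modeling term by constructing the 3-4-5 triangle directly
        m2 = self._model()
        m2.rmse = 40.0
        sig = compose_pixel_error(_g([[30.0]]), m2, agb, field_rel_error=0.0,
                                  modeling_mode="absolute")
        assert sig.sigma_total.values[0, 0] == pytest.approx(50.0)

    def test_field_term_is_21_4_percent_of_agb(self):
        m = self._model()
        m.rmse = 0.0
        sig = compose_pixel_error(_g([[0.0]]), m, _g([[100.0]]))
        assert sig.sigma_field.values[0, 0] == pytest.approx(21.4)
        assert sig.sigma_total.values[0, 0] == pytest.approx(21.4)

    def test_all_zero_components(self):
        m = self._model()
        m.rmse = 0.0
        sig = compose_pixel_error(_g([[0.0]]), m, _g([[0.0]]))
        assert sig.sigma_total.values[0, 0] == 0.0

    def test_quadrature_identity_holds_everywhere(self, rng):
        m = self._model()
        agb = _g(rng.uniform(50, 300, (10, 10)))
        srs = _g(rng.uniform(0, 40, (10, 10)))
        st = compose_pixel_error(srs, m, agb)
        lhs = st.sigma_total.values ** 2
        rhs = (st.sigma_rs.values ** 2 + st.sigma_modeling.values ** 2
               + st.sigma_field.values ** 2)
        assert np.allclose(lhs, rhs)

    def test_total_monotone_in_each_component(self):
        m = self._model()
        base = compose_pixel_error(_g([[10.0]]), m, _g([[100.0]]))
        more_rs = compose_pixel_error(_g([[20.0]]), m, _g([[100.0]]))
        assert more_rs.sigma_total.values[0, 0] > base.sigma_total.values[0, 0]

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compose_pixel_error(_g([[-1.0]]), self._model(), _g([[100.0]]))


class TestSemivariogram:
    def test_white_noise_is_degenerate(self, rng):
        sv = fit_semivariogram(_g(rng.normal(size=(60, 60)), cell=50.0), 2000.0)
        assert sv.degenerate or sv.range_m < 100.0
        assert np.all(sv.rho(np.array([100.0, 500.0])) < 0.1)

    def test_generated_range_recovered_within_half(self):
        f = correlated_field((150, 150), 50.0, 500.0, np.random.default_rng(4))
        sv = fit_semivariogram(_g(f, cell=50.0), 2500.0)
        assert 250.0 < sv.range_m < 750.0

    def test_empirical_bins_match_brute_force_pairs(self, rng):
        z = rng.normal(size=(30, 30))
        g = _g(z, cell=50.0)
        emp = empirical_semivariogram(g, max_lag=500.0, n_bins=5, max_cells=900)
        iy, ix = np.nonzero(np.ones((30, 30), bool))
        xy = np.column_stack([ix, iy]) * 50.0
        vals = z[iy, ix]
        from scipy.spatial.distance import pdist
        d = pdist(xy)
        g2 = pdist(vals[:, None], metric="sqeuclidean") / 2.0
        bins = np.linspace(0, 500.0, 6)
        for _, row in emp.iterrows():
            b = np.digitize(row["lag"], bins) - 1
            sel = (np.digitize(d, bins) - 1) == b
            assert row["gamma"] == pytest.approx(g2[sel].mean(), rel=1e-9)

    def test_rho_is_nonincreasing_and_clamped(self):
        sv = Semivariogram(nugget=0.2, partial_sill=0.8, range_m=400.0)
        d = np.array([0.0, 100.0, 400.0, 1200.0, 1300.0])
        r = sv.rho(d)
        assert np.all(np.diff(r) <= 1e-12)
        assert r[-1] == 0.0  # beyond the practical range 3r


class TestClassVariance:
    def test_two_pixels_uncorrelated(self):
        v, se = class_variance(np.array([1.0, 1.0]), np.array([[0, 0], [1, 0]]))
        assert v == pytest.approx(1.0)

    def test_three_pixels_hand_computed(self):
        v, _ = class_variance(np.array([1.0, 2.0, 3.0]),
                              np.array([[0, 0], [1, 0], [2, 0]]))
        assert v == pytest.approx((1 + 4 + 9) / 6)

    def test_full_correlation_equal_sigmas(self):
        # printed normalisation: sigma^2 (1/(m-1) + 1)
        sv = Semivariogram(0.0, 1.0, 1e12)
        for m in (2, 5, 20):
            v, _ = class_variance(np.full(m, 3.0), np.zeros((m, 2)), sv)
            assert v == pytest.approx(9.0 * (1 / (m - 1) + 1))

    def test_classical_convention_smaller_for_large_m(self):
        sig = np.ones(50)
        xy = np.random.default_rng(0).uniform(0, 5000, (50, 2))
        vp, _ = class_variance(sig, xy, convention="printed")
        vc, _ = class_variance(sig, xy, convention="classical")
        assert vc < vp

    def test_binned_approximation_close_to_exact(self, rng):
        ny = nx = 50
        iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        coords = np.column_stack([ix.ravel(), iy.ravel()]) * 100.0
        sig = rng.uniform(0.5, 2.0, ny * nx)
        sv = Semivariogram(0.1, 0.9, 800.0)
        exact, _ = class_variance(sig, coords, sv, exact_limit=3000)
        binned, _ = class_variance(sig, coords, sv, exact_limit=2499,
                                   n_dist_bins=200)
        assert abs(binned - exact) / exact < 0.01

    def test_single_pixel_rejected(self):
        with pytest.raises(ValueError, match="2 pixels"):
            class_variance(np.array([1.0]), np.array([[0, 0]]))


def _constant_pipeline(value, shape, cell=100.0):
    def pipe(scenes):
        return GridRaster(np.full(shape, float(value)), cell, (0.0, shape[0] * cell))
    return pipe


class TestBootstrapUncertainty:
    def test_identical_iterations_give_zero_sigma(self):
        scenes = [SceneFootprint((i * 1100.0 + 500.0, 2000.0), 1000.0, 5000.0, 0.0)
                  for i in range(4)]
        ref = _g(np.full((40, 40), 15.0))
        mean, sigma, rep = bootstrap_map_uncertainty(
            scenes, _constant_pipeline(15.0, (40, 40)), ref, iterations=5, seed=1)
        assert np.allclose(sigma.values[sigma.mask], 0.0)
        assert np.allclose(mean.values[mean.mask], 15.0)

    def test_two_iteration_sd_matches_hand_computation(self, monkeypatch):
        scenes = [SceneFootprint((i * 1100.0 + 500.0, 2000.0), 1000.0, 5000.0, 0.0)
                  for i in range(4)]
        ref = _g(np.full((40, 40), 15.0))
        outputs = iter([_g(np.full((40, 40), 10.0)), _g(np.full((40, 40), 20.0))])

        def pipe(keep):
            return next(outputs)

        _, sigma, _ = bootstrap_map_uncertainty(scenes, pipe, ref, iterations=2, seed=2)
        assert np.allclose(sigma.values[sigma.mask], np.std([10.0, 20.0]))

    def test_needs_at_least_four_scenes(self):
        with pytest.raises(ValueError, match="4 scenes"):
            bootstrap_map_uncertainty([], _constant_pipeline(1, (5, 5)), _g(np.ones((5, 5))))


class TestLeaveOneSceneOut:
    def test_identical_scenes_perfect_r2(self):
        scenes = [SceneFootprint((1000.0, 2000.0), 1000.0, 5000.0, 0.0),
                  SceneFootprint((3000.0, 2000.0), 1000.0, 5000.0, 0.0)]
        truth = np.tile(np.linspace(5, 30, 40), (40, 1))
        ref = _g(truth)

        def pipe(keep):
            return _g(truth)  # noiseless predictor: exact prediction

        rep = leave_one_scene_out(scenes, pipe, ref)
        assert rep.pooled_r2 == pytest.approx(1.0)
        assert all(rep.per_iteration["r2"] > 0.999)

    def test_pooled_rmse_equals_concatenated_residuals(self):
        scenes = [SceneFootprint((1000.0, 2000.0), 1000.0, 5000.0, 0.0),
                  SceneFootprint((3000.0, 2000.0), 1000.0, 5000.0, 0.0)]
        rng = np.random.default_rng(5)
        truth = rng.uniform(5, 30, (40, 40))
        ref = _g(truth)
        pred_map = truth + rng.normal(0, 2, (40, 40))

        def pipe(keep):
            return _g(pred_map)

        rep = leave_one_scene_out(scenes, pipe, ref)
        mask = np.zeros((40, 40), bool)
        for sc in scenes:
            mask |= scene_cell_mask([sc], ref)
        manual = float(np.sqrt(np.mean((truth[mask] - pred_map[mask]) ** 2)))
        assert rep.pooled_rmse == pytest.approx(manual, rel=1e-9)

    def test_reports_both_mean_and_pooled_r2(self):
        scenes = [SceneFootprint((1000.0, 2000.0), 1000.0, 5000.0, 0.0),
                  SceneFootprint((3000.0, 2000.0), 1000.0, 5000.0, 0.0)]
        rng = np.random.default_rng(6)
        truth = rng.uniform(5, 30, (40, 40))
        ref = _g(truth)

        def pipe(keep):
            return _g(truth + rng.normal(0, 3, (40, 40)))

        rep = leave_one_scene_out(scenes, pipe, ref)
        assert "mean_iteration_r2" in rep.extras
        assert np.isfinite(rep.pooled_r2)
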