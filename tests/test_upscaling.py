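import numpy as np
import pytest

from agbmc import (
    PassthroughModel,
    ScenarioParams,
    SceneConfig,
    TrainConfig,
    ci95,
    forest_mask,
    generate_realizations,
    generate_scene,
    mc_fit_predict,
    relative_uncertainty,
    residual_outlier_mask,
    run_scenario,
    total_carbon,
    uncertainty_screen,
    write_surfaces,
)
from agbmc.upscale import UncertaintySurface


class TestResidualOutlierMask:
    def test_zero_residuals_all_kept(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert residual_outlier_mask(obs, obs).all()

    def test_single_extreme_outlier_removed(self):
        obs = np.zeros(21)
        obs[0] = 10.0
        keep = residual_outlier_mask(obs, np.zeros(21), k=2.0)
        assert not keep[0]
        assert keep[1:].all()

    def test_normal_keep_fraction_near_95_percent(self, rng):
        resid = rng.standard_normal(10_000)
        keep = residual_outlier_mask(resid, np.zeros_like(resid), k=2.0)
        assert keep.mean() == pytest.approx(0.9545, abs=0.01)


class TestCi95:
    def test_constant_stack_is_zero(self):
        assert np.allclose(ci95(np.full((50, 7), 3.0)), 0.0)

    def test_two_point_stack_halfwidth_is_half_gap(self):
        stack = np.tile(np.array([[2.0], [10.0]]), (50, 1))
        assert ci95(stack)[0] == pytest.approx(4.0, abs=0.3)

    def test_normal_stack_matches_196_sigma(self, rng):
        stack = rng.normal(80.0, 10.0, size=(10_000, 5))
        half = ci95(stack)
        assert np.allclose(half, 1.96 * 10.0, rtol=0.03)

    def test_all_nodata_pixel_stays_nodata(self):
        stack = np.ones((10, 3))
        stack[:, 1] = np.nan
        out = ci95(stack)
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_permutation_invariant(self, rng):
        stack = rng.normal(50, 5, size=(200, 4))
        shuffled = stack[rng.permutation(200)]
        assert np.allclose(ci95(stack), ci95(shuffled))


class TestRelativeUncertainty:
    def test_constant_stack_zero_percent(self):
        surf = relative_uncertainty(np.full((20, 3), 40.0))
        assert np.allclose(surf.rel_uncertainty, 0.0)

    def test_mean_below_guard_is_nodata(self):
        surf = relative_uncertainty(np.full((20, 1), 0.5), mean_guard=1.0)
        assert np.isnan(surf.rel_uncertainty[0])

    def test_scale_invariance(self, rng):
        stack = rng.lognormal(3.5, 0.3, size=(500, 6))
        a = relative_uncertainty(stack).rel_uncertainty
        b = relative_uncertainty(stack * 7.0).rel_uncertainty
        assert np.allclose(a, b, rtol=1e-9)

    def test_normal_stack_rel_uncertainty(self, rng):
        stack = rng.normal(100.0, 17.0, size=(10_000, 4))
        surf = relative_uncertainty(stack)
        assert np.allclose(surf.rel_uncertainty, 33.3, atol=1.5)


class TestMasksAndCarbon:
    def test_uncertainty_screen_strictly_below_threshold(self):
        surf = UncertaintySurface(
            mean_agb=np.array([50.0, 50.0, 50.0, 50.0]),
            ci95_halfwidth=np.zeros(4),
            rel_uncertainty=np.array([10.0, 50.0, 90.0, np.nan]),
        )
        assert uncertainty_screen(surf, 50.0).tolist() == [True, False, False, False]

    def test_forest_mask_strict_threshold(self):
        cover = np.array([10.0, 10.1, 0.0])
        assert forest_mask(cover, 10.0).tolist() == [False, True, False]

    @pytest.mark.parametrize("agb, expected", [
        (np.array([100.0]), 48.0),
        (np.array([np.nan, np.nan]), 0.0),
        (np.array([50.0, 150.0]), 96.0),
    ])
    def test_total_carbon(self, agb, expected):
        assert total_carbon(agb, pixel_area_ha=1.0) == pytest.approx(expected)


class TestMcFitPredict:
    def test_zero_error_gives_identical_maps(self, rng):
        base = rng.uniform(10, 100, 40)
        realz = generate_realizations(base, 0.0, n=5, master_seed=1)
        x = base[:, None]
        stack = mc_fit_predict(realz, x, x, TrainConfig(min_leaf_size=5))
        assert np.allclose(stack, stack[0])

    def test_passthrough_identity_recovers_reference(self, rng):
        base = rng.uniform(10, 100, 50)
        realz = generate_realizations(base, 17.0, n=200, master_seed=2)
        stack = mc_fit_predict(realz, base[:, None], base[:, None],
                               learner_factory=PassthroughModel)
        assert np.allclose(stack.mean(axis=0), base)

    def test_noise_propagates_to_stack_variance(self, rng):
        base = rng.uniform(20, 120, 60)
        realz = generate_realizations(base, 17.0, n=20, master_seed=3)
        x = np.column_stack([base, rng.normal(size=60)])
        stack = mc_fit_predict(realz, x, x, TrainConfig(min_leaf_size=10))
        assert stack.std(axis=0).max() > 0.0

    def test_nodata_training_rows_dropped(self, rng):
        base = rng.uniform(10, 100, 40)
        realz = generate_realizations(base, 10.0, n=3, master_seed=4)
        x = base[:, None].copy()
        x[5, 0] = np.nan
        stack = mc_fit_predict(realz, x, np.array([[50.0], [np.nan]]),
                               TrainConfig(min_leaf_size=5))
        assert np.isfinite(stack[:, 0]).all()
        assert np.isnan(stack[:, 1]).all()


@pytest.fixture(scope="module")
def tiny_scene():
    return generate_scene(SceneConfig(
        grid_rows=60, grid_cols=60, plot_spacing=300.0,
        lidar_coverage_fraction=0.5, lidar_strip_width=5, seed=7,
    ))


@pytest.fixture(scope="module")
def tiny_params():
    return ScenarioParams(
        n_realizations=12, seed=5, stage2_max_train=800,
        train_config=TrainConfig(min_leaf_size=25),
    )


class TestScenarios:
    def test_zero_noise_scene_has_near_zero_uncertainty(self):
        scene = generate_scene(SceneConfig(
            grid_rows=60, grid_cols=60, plot_spacing=300.0,
            lidar_coverage_fraction=0.5, lidar_strip_width=5,
            subplot_noise_pct=0.0, geolocation_sd=0.0, seed=9,
        ))
        params = ScenarioParams(n_realizations=8, seed=1, eps_field_pct=0.0,
                                stage2_max_train=500)
        result = run_scenario(scene, "nfi_direct", params)
        assert result.report["mean_rel_uncertainty_pct"] == pytest.approx(0.0, abs=1e-6)

    def test_steep_plots_never_enter_training(self, tiny_scene, tiny_params):
        result = run_scenario(tiny_scene, "nfi_direct", tiny_params)
        rep = result.report
        steep = sum(p.slope_deg > 15.0 for p in tiny_scene.plots)
        assert rep["n_plots_steep_excluded"] == steep
        assert rep["n_plots_usable"] == len(tiny_scene.plots) - steep

    def test_report_counts_and_surfaces(self, tiny_scene, tiny_params, tmp_path):
        result = run_scenario(tiny_scene, "lidar_two_stage", tiny_params)
        rep = result.report
        assert rep["n_plots_on_strips"] >= rep["n_plots_stage1_training"]
        assert rep["n_stage2_training_pixels"] <= rep["n_strip_pixels"]
        assert result.stack.shape == (12, 60, 60)
        fmask = forest_mask(tiny_scene.predictor_layers["tree_cover"])
        assert np.isnan(result.surface.mean_agb[~fmask]).all()
        outdir = write_surfaces(result, tmp_path / "maps")
        assert (outdir / "agb_mean.tif").exists()
        assert (outdir / "report.json").exists()

    def test_screened_variant_trains_on_fewer_pixels(self, tiny_scene, tiny_params):
        full = run_scenario(tiny_scene, "lidar_two_stage", tiny_params)
        screened = run_scenario(tiny_scene, "lidar_two_stage_screened", tiny_params)
        assert (screened.report["n_stage2_training_pixels"]
                <= full.report["n_stage2_training_pixels"])

    def test_unknown_scenario_rejected(self, tiny_scene):
        with pytest.raises(ValueError):
            run_scenario(tiny_scene, "bogus")
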