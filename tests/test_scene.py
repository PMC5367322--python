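"""Synthetic fire scene generator: stand structure, fire effects, sensors."""

import numpy as np
import pytest

from firecarb.scene import (ALLOMETRY, SEVERITY_CODES, VEG_CODES, FieldPlot,
                            InfeasibleTargetError, SceneConfig, filter_plots,
                            generate_scene, generate_trees, plot_agb,
                            simulate_point_cloud, simulate_reflectance,
                            tree_agb_kg, tree_height)


class TestGenerateTrees:
    def test_target_plot_biomass_hit_within_tolerance(self, rng):
        trees = generate_trees(195.8, VEG_CODES["conifer"], rng)
        agb = plot_agb(trees)
        assert 186.0 <= agb <= 205.6
        assert all(t.dbh_cm >= 10.0 for t in trees)
        assert all(t.dbh_cm <= 145.0 + 1e-9 for t in trees)

    def test_single_tree_allometry_identity(self):
        h = float(tree_height(10.0, "conifer"))
        alpha, beta, delta = ALLOMETRY["conifer"]
        assert float(tree_agb_kg(10.0, h, "conifer")) == pytest.approx(
            alpha * 10.0**beta * h**delta)

    def test_sample_mean_tracks_target_over_many_plots(self, rng):
        targets = rng.uniform(50.0, 400.0, size=200)
        realized = np.array([
            plot_agb(generate_trees(t, VEG_CODES["conifer"], rng))
            for t in targets])
        rel = realized / targets
        # every plot within the 5% closure band; mean ratio ~1
        assert np.all((rel > 0.95) & (rel < 1.05))
        se = rel.std(ddof=1) / np.sqrt(rel.size)
        assert abs(rel.mean() - 1.0) < 2 * max(se, 1e-3)

    def test_unreachable_target_signals(self, rng):
        with pytest.raises(InfeasibleTargetError):
            generate_trees(1e6, VEG_CODES["conifer"], rng, max_trees=50)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_trees(0.0, VEG_CODES["conifer"], rng)


class TestSimulatePointCloud:
    def test_return_count_follows_density(self, rng):
        cfg = SceneConfig()
        trees = generate_trees(200.0, VEG_CODES["conifer"], rng)
        t = simulate_point_cloud(trees, cfg, rng=rng)
        assert abs(t.n_returns - 18000) < 5 * np.sqrt(18000)

    def test_treeless_cell_is_all_ground(self, rng):
        cfg = SceneConfig()
        t = simulate_point_cloud([], cfg, rng=rng)
        assert t.n_returns > 0
        assert np.all(t.height_m < 2.0)

    def test_zero_density_yields_flagged_empty_tile(self, rng):
        cfg = SceneConfig(point_density=0.0)
        trees = generate_trees(100.0, VEG_CODES["conifer"], rng)
        t = simulate_point_cloud(trees, cfg, rng=rng)
        assert t.empty_flag and t.n_returns == 0

    def test_high_severity_snags_lose_canopy_but_keep_top(self, rng):
        cfg = SceneConfig()
        trees = generate_trees(250.0, VEG_CODES["conifer"], rng)
        cover = 0.6
        pre = simulate_point_cloud(trees, cfg, severity="high", date="pre",
                                   rng=np.random.default_rng(5), cover=cover)
        post = simulate_point_cloud(trees, cfg, severity="high", date="post",
                                    rng=np.random.default_rng(5), cover=cover)
        n_can_pre = int((pre.height_m > 2).sum())
        n_can_post = int((post.height_m > 2).sum())
        assert n_can_post <= 0.3 * n_can_pre  # >= 70% of canopy returns gone
        assert post.height_m.max() == pytest.approx(pre.height_m.max(), rel=0.02)


class TestSimulateReflectance:
    def test_bare_cell_shows_soil_spectrum(self):
        from firecarb.scene import SPEC_SOIL
        cfg = SceneConfig(reflectance_noise=0.0, cover_noise=0.0)
        agb = np.zeros((2, 2))
        dem = np.full((2, 2), 1230.0)  # mid elevation: no elevation term
        sev = np.zeros((2, 2), dtype=int)
        bands = simulate_reflectance(agb, dem, sev, cfg, "pre",
                                     np.random.default_rng(0))
        assert np.allclose(bands[:, 0, 0], SPEC_SOIL, atol=1e-6)

    def test_ndii_monotone_in_biomass_without_noise(self):
        cfg = SceneConfig(reflectance_noise=0.0, cover_noise=0.0)
        agb = np.array([[50.0, 300.0]])
        dem = np.full((1, 2), 1230.0)
        sev = np.zeros((1, 2), dtype=int)
        b = simulate_reflectance(agb, dem, sev, cfg, "pre",
                                 np.random.default_rng(0))
        ndii = (b[3] - b[4]) / (b[3] + b[4])
        assert ndii[0, 1] > ndii[0, 0]

    def test_ndii_correlates_with_biomass_at_default_noise(self, small_scene):
        sc = small_scene
        unburned = sc.severity == 0
        b = sc.reflectance_pre
        ndii = (b[3] - b[4]) / (b[3] + b[4])
        r = np.corrcoef(ndii[unburned], sc.agb_true_pre[unburned])[0, 1]
        assert r > 0.7

    def test_burn_scar_drops_nir_and_raises_swir(self):
        cfg = SceneConfig(reflectance_noise=0.0, cover_noise=0.0)
        agb = np.array([[300.0, 300.0]])
        dem = np.full((1, 2), 1230.0)
        sev = np.array([[0, 3]])
        pre = simulate_reflectance(agb, dem, sev, cfg, "pre",
                                   np.random.default_rng(0))
        post = simulate_reflectance(agb * np.array([[1.0, 0.15]]), dem, sev,
                                    cfg, "post", np.random.default_rng(0))
        assert post[3, 0, 1] < pre[3, 0, 1]  # NIR drop in the burn scar
        assert post[4, 0, 1] > pre[4, 0, 1]  # SWIR rise in the burn scar
        np.testing.assert_allclose(post[:, 0, 0], pre[:, 0, 0])  # unburned


class TestFilterPlots:
    def _plot(self, pid, fc, err):
        return FieldPlot(plot_id=pid, cell=(0, 0), trees=[],
                         plot_agb_Mg_ha=100.0, fractional_cover=fc,
                         gps_error_m=err)

    def test_field_campaign_attrition(self, small_scene):
        kept = filter_plots(small_scene.plots)
        assert len(small_scene.plots) == 71
        assert len(kept) == 65

    def test_thresholds_disabled_is_identity(self):
        plots = [self._plot(i, 0.01, 99.0) for i in range(5)]
        assert filter_plots(plots, max_gps_error_m=np.inf, min_fc=0.0) == plots

    def test_cover_boundary_is_inclusive(self):
        keep = self._plot(0, 0.10, 1.0)
        drop_fc = self._plot(1, 0.0999, 1.0)
        drop_gps = self._plot(2, 0.5, 2.01)
        kept = filter_plots([keep, drop_fc, drop_gps])
        assert kept == [keep]

    def test_order_preserved(self):
        plots = [self._plot(i, 0.5, 0.1) for i in range(4)]
        assert [p.plot_id for p in filter_plots(plots)] == [0, 1, 2, 3]


class TestSceneInvariants:
    def test_mass_monotonicity_and_exact_consumption(self, small_scene):
        sc = small_scene
        assert np.all(sc.agb_true_post <= sc.agb_true_pre + 1e-9)
        for name, code in SEVERITY_CODES.items():
            cf = sc.config.consumption_fractions.get(name, 0.0)
            m = sc.severity == code
            np.testing.assert_allclose(
                sc.agb_true_pre[m] - sc.agb_true_post[m],
                cf * sc.agb_true_pre[m], rtol=1e-9, atol=1e-9)

    def test_severity_consumption_strictly_ordered(self, small_scene):
        sc = small_scene
        means = []
        consumed = sc.true_consumed_Mg_ha()
        for code in range(4):
            m = (sc.severity == code) & (sc.agb_true_pre > 0)
            frac = consumed[m] / sc.agb_true_pre[m]
            means.append(frac.mean())
        assert means[0] < means[1] < means[2] < means[3]

    def test_severity_fractions_respected_inside_perimeter(self, small_scene):
        sc = small_scene
        n = sc.perimeter.sum()
        for name, code in SEVERITY_CODES.items():
            frac = np.mean(sc.severity[sc.perimeter] == code)
            assert frac == pytest.approx(
                sc.config.severity_fractions[name], abs=1.5 / np.sqrt(n) + 0.01)

    def test_buffer_is_unburned(self, small_scene):
        sc = small_scene
        assert np.all(sc.severity[~sc.perimeter] == 0)

    def test_reproducibility_bit_identical(self):
        cfg = SceneConfig(grid_rows=26, grid_cols=26, buffer_width=6, seed=9)
        a = generate_scene(cfg)
        b = generate_scene(cfg)
        np.testing.assert_array_equal(a.agb_true_pre, b.agb_true_pre)
        np.testing.assert_array_equal(a.reflectance_post, b.reflectance_post)
        ta = a.point_cloud(3, 3, "post")
        tb = b.point_cloud(3, 3, "post")
        np.testing.assert_array_equal(ta.height_m, tb.height_m)
        np.testing.assert_array_equal(ta.intensity, tb.intensity)

    def test_unburned_cells_identical_pre_post(self, small_scene):
        sc = small_scene
        r, c = np.argwhere((sc.severity == 0))[0]
        pre = sc.point_cloud(r, c, "pre")
        post = sc.point_cloud(r, c, "post")
        np.testing.assert_array_equal(pre.height_m, post.height_m)
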