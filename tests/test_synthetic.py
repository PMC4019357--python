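"""Generators: spatial structure, plot geometry, tree lists, censoring."""

import math

import numpy as np
import pytest
from scipy import stats

import standmap
from standmap import synthetic
from standmap.synthetic import (
    MODE_FIA,
    MODE_FIA_LIKE,
    MODE_NFI,
    NONFOREST,
    GridSpec,
    StandParams,
    TreeRecord,
    apply_inventory_protocol,
)


def brute_force_semivariogram(values, coords, lag, tol=1.0):
    """Direct variogram over all pixel pairs whose separation is ~lag."""
    d = np.sqrt(
        (coords[:, None, 0] - coords[None, :, 0]) ** 2
        + (coords[:, None, 1] - coords[None, :, 1]) ** 2
    )
    iu = np.triu_indices(len(values), k=1)
    sel = np.abs(d[iu] - lag) < tol
    diffs = (values[:, None] - values[None, :])[iu][sel]
    return 0.5 * np.mean(diffs**2)


class TestBiomassSurface:
    def test_all_nonforest_without_scattered_trees_is_zero(self):
        grid = GridSpec(10, 10)
        surf = standmap.generate_biomass_surface(
            grid, {"sill": 400, "decay": 0.05, "mean": 80}, 1.0, seed=1,
            scattered_trees=False,
        )
        assert np.all(surf.biomass == 0.0)
        assert np.all(surf.condition == NONFOREST)

    def test_biomass_clipped_nonnegative(self):
        grid = GridSpec(15, 15)
        surf = standmap.generate_biomass_surface(
            grid, {"sill": 400, "decay": 0.05, "mean": 5}, 0.2, seed=2
        )
        assert surf.biomass.min() >= 0.0

    def test_invalid_parameters_rejected(self):
        grid = GridSpec(5, 5)
        with pytest.raises(ValueError):
            standmap.generate_biomass_surface(
                grid, {"sill": -1, "decay": 0.05, "mean": 10}, 0.1, seed=1
            )
        with pytest.raises(ValueError):
            standmap.generate_biomass_surface(
                grid, {"sill": 400, "decay": 0.05, "mean": 10}, 1.5, seed=1
            )

    def test_semivariogram_matches_exponential_model(self):
        # mean far above 0 so clipping is inert; no nonforest carving
        grid = GridSpec(50, 50)
        surf = standmap.generate_biomass_surface(
            grid, {"sill": 400.0, "decay": 0.05, "mean": 150.0}, 0.0, seed=7
        )
        r = surf.to_raster()
        x, y = r.pixel_centers()
        coords = np.column_stack([x, y])
        vals = surf.biomass.ravel()
        for lag in (30.0, 60.0, 90.0):
            gamma_hat = brute_force_semivariogram(vals, coords, lag)
            gamma_true = 400.0 * (1.0 - math.exp(-0.05 * lag))
            assert gamma_hat == pytest.approx(gamma_true, rel=0.20)

    def test_nonforest_biomass_share_hits_target(self, small_surface):
        assert small_surface.nonforest_biomass_share() == pytest.approx(0.25, abs=1e-9)

    def test_reproducible_under_seed(self):
        grid = GridSpec(12, 12)
        kwargs = dict(
            spatial_params={"sill": 400, "decay": 0.05, "mean": 40},
            nonforest_fraction=0.25,
            seed=42,
        )
        a = standmap.generate_biomass_surface(grid, **kwargs)
        b = standmap.generate_biomass_surface(grid, **kwargs)
        np.testing.assert_array_equal(a.biomass, b.biomass)
        assert np.array_equal(a.condition, b.condition)


class TestPlotNetwork:
    def test_single_cluster_geometry(self):
        grid = GridSpec(20, 20)
        (cluster,) = standmap.generate_plot_network(grid, 1, MODE_FIA, seed=3)
        assert len(cluster.subplot_centers) == 4
        cx, cy = cluster.center
        sat_d = [
            math.hypot(x - cx, y - cy) for x, y in cluster.subplot_centers[1:]
        ]
        assert all(d == pytest.approx(7.0) for d in sat_d)
        # satellites themselves sit 7*sqrt(3) apart (120-degree layout)
        (x1, y1), (x2, y2) = cluster.subplot_centers[1:3]
        assert math.hypot(x1 - x2, y1 - y2) == pytest.approx(7 * math.sqrt(3))

    def test_nfi_mode_single_400m2_plot(self):
        grid = GridSpec(20, 20)
        (cluster,) = standmap.generate_plot_network(grid, 1, MODE_NFI, seed=3)
        assert len(cluster.subplot_centers) == 1
        assert cluster.subplot_area == 400.0
        assert cluster.sampled_area_m2 == 400.0

    def test_fia_sampled_area_is_670m2(self):
        grid = GridSpec(20, 20)
        (cluster,) = standmap.generate_plot_network(grid, 1, MODE_FIA, seed=3)
        assert cluster.sampled_area_m2 == pytest.approx(4 * 168.0)

    def test_systematic_lattice_spacing(self):
        grid = GridSpec(100, 100)  # 3 km x 3 km
        clusters = standmap.generate_plot_network(grid, 100, MODE_FIA, seed=5)
        pts = np.array([c.center for c in clusters])
        ideal = math.sqrt(grid.width_m * grid.height_m / 100)
        d = np.sqrt(
            (pts[:, None, 0] - pts[None, :, 0]) ** 2
            + (pts[:, None, 1] - pts[None, :, 1]) ** 2
        )
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert np.all(np.abs(nn - ideal) <= 0.1 * ideal)

    def test_all_subplots_inside_grid(self):
        grid = GridSpec(30, 30)
        clusters = standmap.generate_plot_network(grid, 25, MODE_FIA, seed=6)
        xmin, ymin = grid.origin
        for cl in clusters:
            for x, y in cl.subplot_centers:
                assert xmin <= x <= xmin + grid.width_m
                assert ymin <= y <= ymin + grid.height_m

    def test_capacity_error(self):
        grid = GridSpec(2, 2, pixel_size=30)
        with pytest.raises(ValueError, match="too small|capacity"):
            standmap.generate_plot_network(grid, 500, MODE_FIA, seed=1)

    def test_fia_like_placement_forest_only(self, small_surface):
        clusters = standmap.generate_plot_network(
            small_surface.grid, 10, MODE_FIA_LIKE, seed=8, surface=small_surface
        )
        for cl in clusters:
            assert small_surface.condition_at(*cl.center) == synthetic.FOREST


class TestTreeLists:
    def test_zero_biomass_cluster_empty(self):
        grid = GridSpec(10, 10)
        surf = standmap.generate_biomass_surface(
            grid, {"sill": 400, "decay": 0.05, "mean": 50}, 1.0, seed=1,
            scattered_trees=False,
        )
        (cl,) = standmap.generate_plot_network(grid, 1, MODE_FIA, seed=2)
        trees = standmap.generate_tree_list(cl, surf, StandParams(), seed=3)
        assert trees == []

    def test_weibull_mean_dbh(self, small_surface):
        stand = StandParams(weibull_shape=2.0, weibull_scale=20.0)
        clusters = standmap.generate_plot_network(
            small_surface.grid, 50, MODE_FIA, seed=4
        )
        dbhs = []
        for i, cl in enumerate(clusters):
            for t in standmap.generate_tree_list(cl, small_surface, stand, seed=i):
                dbhs.append(t.dbh_cm)
        assert len(dbhs) > 300
        expected = 20.0 * math.gamma(1.5)
        assert np.mean(dbhs) == pytest.approx(expected, rel=0.05)

    def test_plot_biomass_tracks_surface(self):
        grid = GridSpec(40, 40)
        surf = standmap.generate_biomass_surface(
            grid, {"sill": 2500, "decay": 0.01, "mean": 60}, 0.0, seed=11
        )
        clusters = standmap.generate_plot_network(grid, 220, MODE_FIA, seed=12)
        stand = StandParams()
        sums, locals_ = [], []
        for i, cl in enumerate(clusters):
            trees = standmap.generate_tree_list(cl, surf, stand, seed=1000 + i)
            sums.append(len(trees))
            locals_.append(
                np.mean([surf.biomass_at(x, y) for x, y in cl.subplot_centers])
            )
        rho = stats.spearmanr(sums, locals_).statistic
        assert rho > 0.7

    def test_cluster_outside_extent_raises(self, small_surface):
        bad = standmap.PlotCluster(
            plot_id=0,
            subplot_centers=[(-50.0, -50.0), (-43.0, -50.0), (-57.0, -50.0), (-50.0, -43.0)],
        )
        with pytest.raises(ValueError, match="outside"):
            standmap.generate_tree_list(bad, small_surface, StandParams(), seed=1)

    def test_reproducible(self, small_surface):
        (cl,) = standmap.generate_plot_network(small_surface.grid, 1, MODE_FIA, seed=2)
        a = standmap.generate_tree_list(cl, small_surface, StandParams(), seed=9)
        b = standmap.generate_tree_list(cl, small_surface, StandParams(), seed=9)
        assert a == b


class TestLidarMetrics:
    def test_zero_noise_perfect_rank_correlation(self, small_surface):
        (m,) = standmap.generate_lidar_metrics(
            small_surface, {"exponent": 0.7, "noise_sd": 0.0}, 1, seed=1
        )
        rho = stats.spearmanr(
            m.values.ravel(), small_surface.biomass.ravel()
        ).statistic
        assert rho == pytest.approx(1.0)

    def test_deterministic(self, small_surface):
        a = standmap.generate_lidar_metrics(
            small_surface, {"exponent": 0.7, "noise_sd": 2.0}, 3, seed=5
        )
        b = standmap.generate_lidar_metrics(
            small_surface, {"exponent": 0.7, "noise_sd": 2.0}, 3, seed=5
        )
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_negative_noise_rejected(self, small_surface):
        with pytest.raises(ValueError):
            standmap.generate_lidar_metrics(
                small_surface, {"exponent": 0.7, "noise_sd": -1.0}, 1, seed=1
            )

    def test_noise_calibration_hits_target_r2(self, small_surface):
        sd = synthetic.calibrate_lidar_noise(small_surface, 0.67, seed=3)
        (m,) = standmap.generate_lidar_metrics(
            small_surface, {"exponent": 0.7, "noise_sd": sd}, 1, seed=3
        )
        r = np.corrcoef(m.values.ravel(), small_surface.biomass.ravel())[0, 1]
        assert r**2 == pytest.approx(0.67, abs=0.05)

    def test_metrics_mutually_correlated(self, small_surface):
        ms = standmap.generate_lidar_metrics(
            small_surface, {"exponent": 0.7, "noise_sd": 1.0}, 3, seed=2
        )
        c01 = np.corrcoef(ms[0].values.ravel(), ms[1].values.ravel())[0, 1]
        assert c01 > 0.8


def _tree(cond, sub=0, dbh=20.0):
    return TreeRecord(0, sub, cond, "pine", dbh, 8.0)


class TestInventoryProtocol:
    def test_all_forest_identity(self):
        trees = [_tree("forest") for _ in range(5)]
        assert apply_inventory_protocol(trees, MODE_FIA) == trees

    def test_all_nonforest_empty(self):
        trees = [_tree("nonforest") for _ in range(5)]
        assert apply_inventory_protocol(trees, MODE_FIA) == []

    def test_mixed_plot_matches_exhaustive_filter(self, rng):
        conds = rng.choice(["forest", "nonforest"], size=40)
        subs = rng.integers(0, 4, size=40)
        trees = [_tree(c, sub=int(s)) for c, s in zip(conds, subs)]
        got = apply_inventory_protocol(trees, MODE_FIA)
        expected = [t for t in trees if t.condition != "nonforest"]
        assert got == expected

    def test_nfi_keeps_center_plot_only(self, rng):
        subs = rng.integers(0, 4, size=20)
        trees = [_tree("nonforest", sub=int(s)) for s in subs]
        got = apply_inventory_protocol(trees, MODE_NFI)
        assert got == [t for t in trees if t.subplot_id == 0]

    def test_fia_like_keeps_all(self):
        trees = [_tree("forest"), _tree("nonforest")]
        assert apply_inventory_protocol(trees, MODE_FIA_LIKE) == trees

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            apply_inventory_protocol([], "BOGUS")

    def test_censoring_is_monotone_per_plot(self, small_surface, registry):
        clusters = standmap.generate_plot_network(
            small_surface.grid, 30, MODE_FIA, seed=21
        )
        stand = StandParams()
        area = clusters[0].sampled_area_m2
        for i, cl in enumerate(clusters):
            trees = standmap.generate_tree_list(cl, small_surface, stand, seed=i)
            censored = apply_inventory_protocol(trees, MODE_FIA)
            d_all = standmap.plot_biomass_density(trees, area, "LN_LN", registry)
            d_fia = standmap.plot_biomass_density(censored, area, "LN_LN", registry)
            assert d_fia <= d_all + 1e-12
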