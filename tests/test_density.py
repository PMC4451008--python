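import math

import numpy as np
import pytest
from scipy import stats

from triloci import (
    KernelLevelMap,
    build_all_maps,
    build_map,
    decile_levels,
    estimate_density,
    gaussian_kernel,
    level_statistics,
)


class TestKernel:
    def test_value_at_own_center(self):
        # K(y, y, t=1) = 1/(2 pi)
        assert gaussian_kernel([0.0, 0.0], [0.0, 0.0], 1.0)[0, 0] == pytest.approx(
            1.0 / (2 * math.pi), abs=1e-15
        )

    def test_two_point_density_hand_value(self):
        # f at either of two points distance 2 apart, t=1:
        # (1/2) (1/(2 pi)) (1 + exp(-2))
        f = estimate_density(np.array([[0.0, 0.0], [2.0, 0.0]]), 1.0)
        want = 0.5 / (2 * math.pi) * (1 + math.exp(-2.0))
        assert f([[0.0, 0.0]])[0] == pytest.approx(want, abs=1e-12)
        assert f([[2.0, 0.0]])[0] == pytest.approx(want, abs=1e-12)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            estimate_density(np.zeros((5, 2)), -1.0)

    def test_lattice_integral_close_to_one(self, rng):
        pts = rng.normal(size=(200, 2))
        est = KernelLevelMap(standardize=False, grid_size=256, grid_pad=5.0)
        est.fit(pts)
        assert est.grid_mass() == pytest.approx(1.0, abs=1e-3)

    def test_matches_scipy_kde_on_whitened_sample(self, rng):
        # independent oracle: scipy's covariance-scaled KDE equals the
        # isotropic kernel when the sample covariance is the identity
        pts = rng.normal(size=(300, 2))
        pts -= pts.mean(axis=0)
        L = np.linalg.cholesky(np.cov(pts.T))
        white = pts @ np.linalg.inv(L).T  # np.cov(white.T) == I
        t = 0.17
        kde = stats.gaussian_kde(white.T, bw_method=math.sqrt(t))
        mine = estimate_density(white, t)
        query = rng.normal(size=(40, 2))
        np.testing.assert_allclose(mine(query), kde(query.T), rtol=1e-10)


class TestDecileLevels:
    def test_strictly_ranked_points(self):
        f = np.arange(10, 0, -1, dtype=float)  # point 0 densest
        levels = decile_levels(f)
        np.testing.assert_array_equal(levels, np.arange(1, 11))

    def test_nesting_and_mass_calibration(self, rng):
        for M in (10, 37, 200):
            f = rng.uniform(size=M)
            levels = decile_levels(f)
            card = np.array([(levels <= k).sum() for k in range(1, 11)])
            assert np.all(np.diff(card) >= 0)
            assert card[-1] == M
            assert np.all(np.abs(card / M - np.arange(1, 11) / 10) <= 1.0 / M)

    def test_uniform_square_median_region_covers_half(self, rng):
        # Monte-Carlo coverage oracle: fresh uniform points fall inside the
        # 50% highest-density region about half the time
        pts = rng.uniform(size=(5000, 2))
        est = KernelLevelMap(standardize=False, grid_size=0).fit(pts)
        thr = np.sort(est.f_points_)[::-1][(est.levels_ <= 5).sum() - 1]
        fresh = rng.uniform(size=(5000, 2))
        coverage = np.mean(est.field_(fresh) >= thr)
        assert coverage == pytest.approx(0.5, abs=0.05)

    def test_bivariate_normal_median_region_boundary(self, rng):
        # closed-form HDR of the standard normal: the 50% region is a disk
        # of squared radius 2 ln 2
        pts = rng.standard_normal((5000, 2))
        est = KernelLevelMap(standardize=False, grid_size=0).fit(pts)
        u5 = est.levels_ <= 5
        # average over the 1% lowest-density members: the boundary shell
        order = np.argsort(est.f_points_[u5])[: max(1, int(0.01 * u5.sum()))]
        r_sq = np.sum(pts[u5][order] ** 2, axis=1).mean()
        assert r_sq == pytest.approx(2 * math.log(2), abs=0.1)


class TestLevelStatistics:
    def test_all_points_identical(self):
        pts = np.tile([1.5, -2.0], (20, 1))
        levels = np.repeat(np.arange(1, 11), 2)
        st_ = level_statistics(pts, levels)
        np.testing.assert_allclose(st_.mu, np.tile([1.5, -2.0], (10, 1)))
        np.testing.assert_allclose(st_.sigma, 0.0)

    def test_four_points_match_direct_arithmetic(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
        levels = decile_levels(np.array([4.0, 3.0, 2.0, 1.0]))
        st_ = level_statistics(pts, levels)
        assert st_.card[-1] == 4
        np.testing.assert_allclose(st_.mu[-1], pts.mean(axis=0))
        np.testing.assert_allclose(st_.sigma[-1], pts.std(axis=0))  # population SD
        # smallest level holds only the densest point
        np.testing.assert_allclose(st_.mu[0], pts[0])

    def test_undefined_below_ten_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [1.0, 3.0]])
        levels = decile_levels(np.array([4.0, 3.0, 2.0, 1.0]))
        st_ = level_statistics(pts, levels)
        assert st_.undefined.sum() == 0 or st_.card[0] > 0  # cumulative regions
        assert np.all(st_.card[1:] >= st_.card[:-1])


class TestBuildMap:
    def test_battery_has_nine_maps(self, moderate_dataset):
        battery = build_all_maps(moderate_dataset)
        assert len(battery) == 9
        for dmap in battery.values():
            assert dmap.stats.card[-1] == dmap.M

    def test_determinism(self, moderate_dataset):
        m1 = build_map(moderate_dataset, "d_rg", "theta_r")
        m2 = build_map(moderate_dataset, "d_rg", "theta_r")
        np.testing.assert_array_equal(m1.levels, m2.levels)

    def test_destandardized_top_level_mean_is_raw_mean(self, moderate_dataset):
        dmap = build_map(moderate_dataset, "d_rb", "theta_g", grid_size=0)
        np.testing.assert_allclose(
            dmap.stats.mu[-1], dmap.points_raw.mean(axis=0), atol=1e-9
        )

    def test_refuses_small_datasets(self, moderate_dataset):
        small = moderate_dataset.subset(np.arange(6))
        with pytest.raises(ValueError, match="at least 10"):
            build_map(small, "d_rg", "theta_r")

    def test_invalid_axis_ids(self, moderate_dataset):
        with pytest.raises(ValueError):
            build_map(moderate_dataset, "theta_r", "theta_r")
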