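"""KDE hypervolumes: bandwidths, Monte Carlo volume, overlap and distance."""

import numpy as np
import pytest

from spechvol import (DegenerateDataError, InvalidArgumentError,
                      centroid_distance, fit_hypervolume, grid_volume_oracle,
                      overlap_jaccard, silverman_bandwidths)


class TestSilvermanBandwidths:
    def test_closed_form_d1_n100_unit_sd(self, rng):
        x = rng.normal(size=(100, 1))
        x = (x - x.mean()) / x.std(ddof=1)  # force sample sd exactly 1
        h = silverman_bandwidths(x)
        assert h[0] == pytest.approx((4 / 3) ** 0.2 * 100 ** -0.2, abs=1e-12)
        assert h[0] == pytest.approx(0.42169, abs=1e-4)

    def test_scaling_linearity(self, rng):
        X = rng.normal(size=(50, 3))
        assert np.allclose(silverman_bandwidths(4.0 * X),
                           4.0 * silverman_bandwidths(X), atol=1e-12)

    def test_closed_form_d3_n9(self, rng):
        X = rng.normal(size=(9, 3))
        sd = X.std(axis=0, ddof=1)
        expected = sd * (4 / 5) ** (1 / 7) * 9 ** (-1 / 7)
        assert np.allclose(silverman_bandwidths(X), expected, atol=1e-12)

    def test_zero_spread_dimension_raises(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(DegenerateDataError):
            silverman_bandwidths(X)


class TestFitHypervolume:
    def test_included_mass_matches_quantile(self, rng):
        hv = fit_hypervolume(rng.normal(size=(200, 2)), 0.95, n_mc=10_000, seed=2)
        frac = np.mean(hv.mc_densities >= hv.threshold_density)
        ci = 2.576 * np.sqrt(0.95 * 0.05 / 10_000) + 1 / 10_000
        assert abs(frac - 0.95) <= ci

    def test_identical_points_raise_without_jitter(self):
        X = np.ones((10, 2))
        with pytest.raises(DegenerateDataError):
            fit_hypervolume(X, n_mc=1000)
        hv = fit_hypervolume(X, n_mc=1000, jitter=1e-9)
        assert hv.volume > 0

    def test_invalid_mass_quantile_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            fit_hypervolume(rng.normal(size=(10, 2)), mass_quantile=1.0, n_mc=1000)

    def test_seeded_refit_is_bit_identical(self, rng):
        X = rng.normal(size=(40, 3))
        a = fit_hypervolume(X, n_mc=2000, seed=11)
        b = fit_hypervolume(X, n_mc=2000, seed=11)
        assert a.volume == b.volume
        assert np.array_equal(a.mc_densities, b.mc_densities)

    def test_scaling_equivariance(self, rng):
        X = rng.normal(size=(60, 3))
        v1 = fit_hypervolume(X, n_mc=2000, seed=5).volume
        v2 = fit_hypervolume(2.5 * X, n_mc=2000, seed=5).volume
        assert v2 == pytest.approx(2.5 ** 3 * v1, rel=1e-12)

    def test_translation_invariance(self, rng):
        X = rng.normal(size=(60, 2))
        v1 = fit_hypervolume(X, n_mc=2000, seed=5).volume
        v2 = fit_hypervolume(X + 50.0, n_mc=2000, seed=5).volume
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_volume_non_decreasing_in_mass_quantile(self, rng):
        X = rng.normal(size=(80, 2))
        vols = [fit_hypervolume(X, q, n_mc=4000, seed=3).volume
                for q in (0.5, 0.8, 0.95, 0.99)]
        assert np.all(np.diff(vols) >= 0)

    def test_expected_volume_grows_with_sample_size(self, rng):
        # motivates the fixed-size resampling protocol; the bias is clearest
        # in the 3-D small-n regime the protocol operates in
        small, large = [], []
        for s in range(80):
            small.append(fit_hypervolume(rng.standard_normal((9, 3)),
                                         n_mc=2000, seed=s).volume)
            large.append(fit_hypervolume(rng.standard_normal((72, 3)),
                                         n_mc=2000, seed=s).volume)
        diff = np.mean(large) - np.mean(small)
        se = np.sqrt(np.var(large) / 80 + np.var(small) / 80)
        assert diff > 2 * se


class TestGridOracle:
    def test_single_point_forced_bandwidth_hdi(self):
        # 95% HDI of N(0,1) has width 2 * 1.96
        v = grid_volume_oracle(np.array([[0.0]]), 0.95, grid_step=0.001,
                               bandwidths=1.0)
        assert v == pytest.approx(2 * 1.959964, abs=0.01)

    def test_first_order_grid_convergence(self, rng):
        x = rng.normal(size=(300, 1))
        exact = grid_volume_oracle(x, 0.95, grid_step=0.0005)
        err_coarse = abs(grid_volume_oracle(x, 0.95, grid_step=0.08) - exact)
        err_fine = abs(grid_volume_oracle(x, 0.95, grid_step=0.04) - exact)
        assert err_fine <= err_coarse + 1e-9

    def test_dimension_limit(self, rng):
        with pytest.raises(InvalidArgumentError):
            grid_volume_oracle(rng.normal(size=(10, 3)), 0.95, 0.1)

    @pytest.mark.parametrize("maker", [
        lambda r: r.uniform(0, 1, size=(800, 2)),
        lambda r: r.normal(size=(800, 2)),
        lambda r: np.vstack([r.normal(0, 0.3, size=(400, 2)),
                             r.normal(4, 0.3, size=(400, 2))]),
    ], ids=["uniform-square", "gaussian", "two-cluster"])
    def test_monte_carlo_agrees_with_grid_oracle(self, rng, maker):
        pts = maker(rng)
        mc = fit_hypervolume(pts, 0.95, n_mc=30_000, seed=7).volume
        grid = grid_volume_oracle(pts, 0.95, grid_step=0.02)
        assert mc == pytest.approx(grid, rel=0.05)


class TestOverlapAndDistance:
    def test_self_overlap_is_one(self, rng):
        hv = fit_hypervolume(rng.normal(size=(100, 2)), n_mc=5000, seed=1)
        assert overlap_jaccard(hv, hv) == pytest.approx(1.0, abs=0.02)

    def test_distant_clusters_do_not_overlap(self, rng):
        a = fit_hypervolume(rng.normal(0, 1, size=(100, 2)), n_mc=2000, seed=1)
        offset = 100 * max(a.bandwidths)
        b = fit_hypervolume(rng.normal(0, 1, size=(100, 2)) + offset,
                            n_mc=2000, seed=2)
        assert overlap_jaccard(a, b) < 0.01

    def test_half_shifted_squares_match_grid_jaccard(self, rng):
        pa = rng.uniform([0, 0], [1, 1], size=(1000, 2))
        pb = rng.uniform([0.5, 0], [1.5, 1], size=(1000, 2))
        a = fit_hypervolume(pa, 0.95, n_mc=20_000, seed=3)
        b = fit_hypervolume(pb, 0.95, n_mc=20_000, seed=4)
        mc_jaccard = overlap_jaccard(a, b)
        grid_jaccard = self._grid_jaccard(a, b, step=0.02)
        assert mc_jaccard == pytest.approx(grid_jaccard, rel=0.10)

    @staticmethod
    def _grid_jaccard(a, b, step):
        """Independent Jaccard via dense-grid membership of both level sets."""
        lo = np.minimum(a.points.min(axis=0), b.points.min(axis=0)) - 1.0
        hi = np.maximum(a.points.max(axis=0), b.points.max(axis=0)) + 1.0
        gx, gy = np.meshgrid(np.arange(lo[0], hi[0], step),
                             np.arange(lo[1], hi[1], step), indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        in_a, in_b = a.contains(grid), b.contains(grid)
        return np.count_nonzero(in_a & in_b) / np.count_nonzero(in_a | in_b)

    def test_centroid_distance_pythagoras(self, rng):
        base = rng.normal(size=(50, 2))
        a = fit_hypervolume(base, n_mc=1000, seed=1)
        b = fit_hypervolume(base + np.array([3.0, 4.0]), n_mc=1000, seed=1)
        assert centroid_distance(a, b) == pytest.approx(5.0, abs=1e-10)
        assert centroid_distance(a, a) == 0.0

    def test_centroid_distance_translation_equivariance(self, rng):
        pa, pb = rng.normal(size=(30, 3)), rng.normal(size=(30, 3)) + 1.0
        a, b = (fit_hypervolume(p, n_mc=1000, seed=1) for p in (pa, pb))
        a2, b2 = (fit_hypervolume(p + 7.0, n_mc=1000, seed=1) for p in (pa, pb))
        assert centroid_distance(a, b) == pytest.approx(
            centroid_distance(a2, b2), abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        a = fit_hypervolume(rng.normal(size=(20, 2)), n_mc=1000, seed=1)
        b = fit_hypervolume(rng.normal(size=(20, 3)), n_mc=1000, seed=1)
        with pytest.raises(InvalidArgumentError):
            overlap_jaccard(a, b)
        with pytest.raises(InvalidArgumentError):
            centroid_distance(a, b)
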