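"""Bayesian point-supervision loss: likelihoods, posteriors, losses.

The vectorized implementations are checked against naive scalar oracles
(element-by-element Gaussian evaluation, per-column normalization, double
loops over annotations x cells) on small random configurations.
"""

import math

import numpy as np
import pytest

from rapecount.annotations import PointAnnotationSet
from rapecount.density_loss import (
    DensityMap,
    LossConfig,
    background_likelihood,
    background_point,
    bayes_loss,
    bayes_loss_and_grad,
    bayes_plus_loss,
    likelihood_matrix,
    make_pixel_grid,
    posterior_from_points,
    posterior_matrix,
)


# ---------------------------------------------------------------- oracles
def gaussian2d_scalar(x, z, sigma):
    d2 = (x[0] - z[0]) ** 2 + (x[1] - z[1]) ** 2
    return math.exp(-d2 / (2 * sigma**2)) / (2 * math.pi * sigma**2)


def naive_likelihood(grid, z, sigma):
    out = np.empty((len(z), grid.m))
    for n, zn in enumerate(z):
        for m, xm in enumerate(grid.locations):
            out[n, m] = gaussian2d_scalar(xm, zn, sigma)
    return out


def naive_bayes_loss(probs, dvec, targets):
    loss = 0.0
    for n in range(probs.shape[0]):
        e = 0.0
        for m in range(probs.shape[1]):
            e += probs[n, m] * dvec[m]
        loss += abs(targets[n] - e)
    return loss


def random_config(rng, max_side=16, max_pts=6):
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    grid = make_pixel_grid(h, w, 1)
    n = int(rng.integers(1, max_pts + 1))
    z = rng.random((n, 2)) * [w, h]
    return grid, z


# ---------------------------------------------------------------- grid
class TestPixelGrid:
    def test_counts_and_stride(self):
        g = make_pixel_grid(256, 256, 8)
        assert (g.height, g.width, g.m) == (32, 32, 1024)

    def test_cell_centers_enumerated(self):
        g = make_pixel_grid(2, 2, 1)
        expected = [(0.5, 0.5), (1.5, 0.5), (0.5, 1.5), (1.5, 1.5)]
        assert [tuple(p) for p in g.locations] == expected

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            make_pixel_grid(250, 256, 8)

    def test_pixel_to_grid_coordinate(self):
        # a point at pixel (128, 64) lands at grid coordinate (16, 8)
        pts = PointAnnotationSet("p", ((128.0, 64.0),))
        assert tuple(pts.asarray()[0] / 8) == (16.0, 8.0)


# ---------------------------------------------------------------- likelihood
class TestLikelihood:
    def test_value_at_mean(self):
        grid = make_pixel_grid(1, 1, 1)  # single cell at (0.5, 0.5)
        lik = likelihood_matrix(grid, np.array([[0.5, 0.5]]), sigma=1.0)
        assert lik[0, 0] == pytest.approx(1 / (2 * math.pi), rel=1e-12)

    def test_isotropy(self):
        grid = make_pixel_grid(3, 3, 1)
        lik = likelihood_matrix(grid, np.array([[1.5, 1.5]]), sigma=0.7)
        row = lik[0].reshape(3, 3)
        assert row[1, 0] == pytest.approx(row[1, 2], rel=1e-12)
        assert row[0, 1] == pytest.approx(row[2, 1], rel=1e-12)

    def test_matches_scalar_oracle(self, rng):
        grid = make_pixel_grid(4, 4, 1)
        z = rng.random((2, 2)) * 4
        lik = likelihood_matrix(grid, z, sigma=2.0)
        np.testing.assert_allclose(lik, naive_likelihood(grid, z, 2.0), atol=1e-12)

    def test_empty_points_give_empty_matrix(self):
        grid = make_pixel_grid(4, 4, 1)
        assert likelihood_matrix(grid, np.empty((0, 2)), 1.0).shape == (0, 16)


# ---------------------------------------------------------------- background
class TestBackgroundGeometry:
    def test_point_already_at_distance_d(self):
        out = background_point(np.array([3.0, 4.0]), np.array([0.0, 0.0]), 5.0)
        np.testing.assert_allclose(out, [3.0, 4.0], atol=1e-12)

    def test_point_beyond_d_projected_back(self):
        out = background_point(np.array([6.0, 8.0]), np.array([0.0, 0.0]), 5.0)
        np.testing.assert_allclose(out, [3.0, 4.0], atol=1e-12)

    def test_degenerate_pixel_on_annotation(self):
        z = np.array([1.0, 1.0])
        out = background_point(z.copy(), z, 5.0)
        np.testing.assert_allclose(out, z)

    def test_background_likelihood_peak_and_tail(self):
        grid = make_pixel_grid(1, 2, 1)  # cells at (0.5,0.5), (1.5,0.5)
        z = np.array([[0.5, 0.5]])
        d = 1.0
        bg = background_likelihood(grid, z, sigma=1.0, d=d)
        # second cell sits exactly at distance d: 1/sqrt(2 pi)
        assert bg[1] == pytest.approx(1 / math.sqrt(2 * math.pi), rel=1e-12)
        far = make_pixel_grid(1, 2, 1)
        far_bg = background_likelihood(
            far, np.array([[-1e4, 0.5]]), sigma=1.0, d=d
        )
        assert far_bg.max() < 1e-300  # Gaussian tail vanishes

    def test_direct_evaluation(self):
        # sigma=2, d=6, distance 2 -> (1/(sqrt(2 pi) 2)) exp(-16/8)
        grid = make_pixel_grid(1, 1, 1)
        z = np.array([[2.5, 0.5]])  # distance 2 from the (0.5, 0.5) cell
        bg = background_likelihood(grid, z, sigma=2.0, d=6.0)
        expect = (1 / (math.sqrt(2 * math.pi) * 2)) * math.exp(-16 / 8)
        assert bg[0] == pytest.approx(expect, rel=1e-12)

    def test_no_annotations_is_an_error(self):
        grid = make_pixel_grid(2, 2, 1)
        with pytest.raises(ValueError):
            background_likelihood(grid, np.empty((0, 2)), 1.0, 1.0)


# ---------------------------------------------------------------- posterior
class TestPosterior:
    def test_single_label_is_all_ones(self):
        grid = make_pixel_grid(3, 3, 1)
        lik = likelihood_matrix(grid, np.array([[1.0, 1.0]]), 0.5)
        post = posterior_matrix(lik)
        np.testing.assert_allclose(post.probs, 1.0, atol=1e-12)

    def test_equidistant_pixel_splits_evenly(self):
        grid = make_pixel_grid(1, 3, 1)  # middle cell at (1.5, 0.5)
        z = np.array([[0.5, 0.5], [2.5, 0.5]])
        post = posterior_matrix(likelihood_matrix(grid, z, 1.0))
        np.testing.assert_allclose(post.probs[:, 1], [0.5, 0.5], atol=1e-12)

    def test_matches_percolumn_normalization_oracle(self, rng):
        lik = rng.random((3, 25)) + 1e-3
        post = posterior_matrix(lik)
        oracle = lik / lik.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(post.probs, oracle, atol=1e-10)

    @pytest.mark.parametrize("use_background", [False, True])
    def test_columns_sum_to_one_100_random_configs(self, use_background):
        rng = np.random.default_rng(99)
        for trial in range(100):
            grid, z = random_config(rng)
            sigma = float(rng.choice([0.1, 0.5, 2.0, 10.0]))
            cfg = LossConfig(sigma=sigma, background_ratio=0.3,
                             use_background=use_background)
            post = posterior_from_points(grid, z, cfg, points_in_pixels=False)
            sums = post.probs.sum(axis=0)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert (post.probs >= 0).all()

    def test_log_space_survives_sigma_0_1_on_32x32(self):
        # one corner point, sigma far below the grid extent: naive Gaussians
        # underflow to zero across most of the grid
        grid = make_pixel_grid(32, 32, 1)
        z = np.array([[0.5, 0.5]])
        cfg = LossConfig(sigma=0.1, background_ratio=0.5, use_background=True)
        post = posterior_from_points(grid, z, cfg, points_in_pixels=False)
        assert np.isfinite(post.probs).all()
        np.testing.assert_allclose(post.probs.sum(axis=0), 1.0, atol=1e-6)

    def test_zero_column_raises_with_cell_index(self):
        lik = np.array([[0.5, 0.0], [0.5, 0.0]])
        with pytest.raises(FloatingPointError, match="1"):
            posterior_matrix(lik)


# ---------------------------------------------------------------- losses
class TestBayesLoss:
    def setup_method(self):
        self.cfg = LossConfig(sigma=2.0, background_ratio=0.3)

    def _posterior(self, rng, h, w, n, use_background):
        grid = make_pixel_grid(h, w, 1)
        z = rng.random((n, 2)) * [w, h]
        cfg = LossConfig(sigma=2.0, background_ratio=0.3,
                         use_background=use_background)
        return posterior_from_points(grid, z, cfg, points_in_pixels=False)

    def test_zero_map_costs_n(self, rng):
        post = self._posterior(rng, 6, 6, 3, use_background=False)
        D = DensityMap(np.zeros((6, 6)))
        assert bayes_loss(post, D, self.cfg) == pytest.approx(3.0, abs=1e-12)

    def test_single_point_unit_mass_costs_zero(self, rng):
        post = self._posterior(rng, 5, 5, 1, use_background=False)
        values = rng.random((5, 5))
        D = DensityMap(values / values.sum())
        assert bayes_loss(post, D, self.cfg) == pytest.approx(0.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        post = self._posterior(rng, 12, 12, 4, use_background=False)
        D = DensityMap(rng.random((12, 12)))
        oracle = naive_bayes_loss(post.probs, D.values.ravel(),
                                  np.ones(post.probs.shape[0]))
        assert bayes_loss(post, D, self.cfg) == pytest.approx(oracle, abs=1e-6)

    def test_plus_zero_map_costs_n(self, rng):
        post = self._posterior(rng, 6, 6, 5, use_background=True)
        D = DensityMap(np.zeros((6, 6)))
        assert bayes_plus_loss(post, D, self.cfg) == pytest.approx(5.0, abs=1e-12)

    def test_plus_matches_double_loop_oracle(self, rng):
        post = self._posterior(rng, 10, 10, 3, use_background=True)
        D = DensityMap(rng.random((10, 10)))
        targets = np.concatenate([[0.0], np.ones(3)])
        oracle = naive_bayes_loss(post.probs, D.values.ravel(), targets)
        assert bayes_plus_loss(post, D, self.cfg) == pytest.approx(oracle, abs=1e-6)

    def test_mass_on_background_cells_costs_n_plus_mass(self):
        # all density far from the single annotation: posterior there is
        # essentially pure background, so loss ~ N + total mass
        grid = make_pixel_grid(1, 40, 1)
        z = np.array([[0.5, 0.5]])
        cfg = LossConfig(sigma=0.5, background_ratio=1.0, use_background=True,
                         d_absolute=3.0)
        post = posterior_from_points(grid, z, cfg, points_in_pixels=False)
        values = np.zeros((1, 40))
        values[0, -5:] = 2.0  # mass 10 at the far end
        loss = bayes_plus_loss(post, DensityMap(values), cfg)
        assert loss == pytest.approx(1.0 + 10.0, rel=1e-3)

    def test_shape_mismatch_rejected(self, rng):
        post = self._posterior(rng, 4, 4, 2, use_background=False)
        with pytest.raises(ValueError):
            bayes_loss(post, DensityMap(np.zeros((5, 5))), self.cfg)

    def test_background_row_required_and_refused(self, rng):
        plain = self._posterior(rng, 4, 4, 2, use_background=False)
        aug = self._posterior(rng, 4, 4, 2, use_background=True)
        D = DensityMap(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            bayes_plus_loss(plain, D, self.cfg)
        with pytest.raises(ValueError):
            bayes_loss(aug, D, self.cfg)


class TestLossProperties:
    def test_expected_counts_conserve_total_mass(self, rng):
        # with the background row, posteriors sum to 1 per cell, so the
        # expected counts over all labels add up to the map's total mass
        for _ in range(20):
            grid, z = random_config(rng)
            cfg = LossConfig(sigma=float(rng.uniform(0.3, 4.0)),
                             background_ratio=0.5, use_background=True)
            post = posterior_from_points(grid, z, cfg, points_in_pixels=False)
            dvec = rng.random(grid.m)
            expected = post.probs @ dvec
            assert expected.sum() == pytest.approx(dvec.sum(), abs=1e-9)

    def test_expected_counts_linear_in_density(self, rng):
        grid, z = random_config(rng)
        cfg = LossConfig(sigma=1.0, background_ratio=0.4, use_background=True)
        post = posterior_from_points(grid, z, cfg, points_in_pixels=False)
        dvec = rng.random(grid.m)
        base = post.probs @ dvec
        for t in (0.0, 0.5, 3.0):
            np.testing.assert_allclose(post.probs @ (t * dvec), t * base,
                                       atol=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        grid, z = random_config(rng, max_side=6, max_pts=3)
        cfg = LossConfig(sigma=1.0, background_ratio=0.5, use_background=True)
        post = posterior_from_points(grid, z, cfg, points_in_pixels=False)
        values = rng.random((grid.height, grid.width)) + 0.5
        loss, grad = bayes_loss_and_grad(post, DensityMap(values), cfg)
        eps = 1e-6
        for _ in range(5):
            i = int(rng.integers(grid.height))
            j = int(rng.integers(grid.width))
            vp = values.copy(); vp[i, j] += eps
            vm = values.copy(); vm[i, j] -= eps
            lp, _ = bayes_loss_and_grad(post, DensityMap(vp), cfg)
            lm = bayes_loss_and_grad(post, DensityMap(vm), cfg)[0]
            num = (lp - lm) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-4)

    def test_unannotated_image_targets_empty_map(self):
        cfg = LossConfig()
        values = np.full((4, 4), 0.25)
        loss, grad = bayes_loss_and_grad(None, DensityMap(values), cfg)
        assert loss == pytest.approx(4.0)
        np.testing.assert_allclose(grad, 1.0)
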