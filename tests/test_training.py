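"""Augmentation, balanced sampling, MLP training, doublet filter."""

import math

import numpy as np
import pytest

from sortcyte import (AugmentConfig, MLPArchitecture, SyntheticConfig,
                      TrainConfig, augment, balanced_batch, doublet_filter,
                      doublet_label, estimate_background, init_mlp,
                      knee_from_curve, loss_and_grads, lr_screen,
                      make_two_class_dataset, median_tilt, mlp_forward,
                      simulate_event_stream, train)
from sortcyte.synthetic import GroundTruth
from sortcyte.training import LRScreenResult

from _geometry import circle_polygon, rect_polygon


class TestEstimateBackground:
    def test_constant_image(self):
        img = np.full((80, 250), 39.0)
        assert estimate_background(img) == (39.0, 0.0)

    def test_noise_sd_recovered(self, rng):
        img = 39.0 + rng.normal(0.0, 3.0, (80, 250))
        _, sd = estimate_background(img)
        assert 2.7 <= sd <= 3.3

    def test_strip_geometry(self):
        """Pixels below the strip never influence the estimate."""
        img = np.full((80, 250), 39.0)
        img[10:, :] = 200.0
        mean, sd = estimate_background(img, strip_rows=10)
        assert mean == 39.0 and sd == 0.0

    def test_strip_taller_than_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((5, 10)), strip_rows=10)


class TestMedianTilt:
    def test_small_set(self):
        contours = [rect_polygon(20, 8, a) for a in (0, 10, 20)]
        med, n_degen = median_tilt(contours)
        assert med == pytest.approx(10.0, abs=0.2)
        assert n_degen == 0

    def test_generator_default_median_near_11_degrees(self):
        cfg = SyntheticConfig(sample_concentration=50e6, avalanche_rate=0.0)
        rng = np.random.default_rng(4)
        _, truths = simulate_event_stream(cfg, 2.5, rng, render=False)
        tilts = np.array([t.true_tilt_deg for t in truths])
        assert len(tilts) >= 1000
        assert abs(np.median(tilts) - 11.0) <= 1.0

    def test_all_circles_degenerate(self):
        med, n_degen = median_tilt([circle_polygon(6.0)] * 3)
        assert med == 0.0 and n_degen == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_tilt([])


class TestAugment:
    def test_identity_is_bit_exact_noop(self, rng):
        img = rng.integers(0, 255, (36, 36)).astype(np.uint8)
        out = augment(img, AugmentConfig.identity(), rng)
        assert np.array_equal(out, img)

    def test_vertical_flip_involution(self, rng):
        cfg = AugmentConfig(rotation_deg=0, shift_lr=0, shift_ud=0,
                            brightness_add=0, brightness_mult=(1, 1),
                            gauss_noise_sd=0, vflip=True)
        img = rng.integers(0, 255, (36, 36)).astype(np.uint8)
        # seed chosen so the flip branch triggers on the first draw
        seed = next(s for s in range(100)
                    if np.random.default_rng(s).random() < 0.5)
        once = augment(img, cfg, np.random.default_rng(seed))
        assert np.array_equal(once, img[::-1, :])
        twice = augment(once, cfg, np.random.default_rng(seed))
        assert np.array_equal(twice, img)

    def test_brightness_clipped_to_255(self, rng):
        cfg = AugmentConfig(rotation_deg=0, shift_lr=0, shift_ud=0,
                            brightness_add=0, brightness_mult=(2.0, 2.0),
                            gauss_noise_sd=0, vflip=False)
        img = np.full((8, 8), 250, np.uint8)
        assert np.all(augment(img, cfg, rng) == 255)

    def test_deterministic_under_seed(self):
        img = np.random.default_rng(0).integers(0, 255, (36, 36)).astype(np.uint8)
        cfg = AugmentConfig()
        a = augment(img, cfg, np.random.default_rng(9))
        b = augment(img, cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_output_dtype_and_range(self, rng):
        img = rng.integers(0, 255, (36, 36)).astype(np.uint8)
        out = augment(img, AugmentConfig(), rng)
        assert out.dtype == np.uint8 and out.shape == img.shape


class TestBalancedBatch:
    def test_equal_quota(self, rng):
        groups = [np.arange(0, 50), np.arange(50, 90), np.arange(90, 200)]
        batch = balanced_batch(groups, 30, rng)
        assert len(batch) == 30
        counts = [np.sum((batch >= g[0]) & (batch <= g[-1])) for g in groups]
        assert counts == [10, 10, 10]

    def test_small_group_sampled_with_replacement(self, rng):
        groups = [np.arange(5)]
        batch = balanced_batch(groups, 10, rng)
        assert len(batch) == 10
        assert len(np.unique(batch)) <= 5

    def test_remainder_deterministic(self, rng):
        groups = [np.arange(10), np.arange(10, 20), np.arange(20, 30)]
        batch = balanced_batch(groups, 32, rng)
        counts = [np.sum((batch >= 10 * i) & (batch < 10 * (i + 1)))
                  for i in range(3)]
        assert counts == [11, 11, 10]  # remainder goes to the first groups

    def test_reproducible_under_seed(self):
        groups = [np.arange(30), np.arange(30, 60)]
        a = balanced_batch(groups, 16, np.random.default_rng(3))
        b = balanced_batch(groups, 16, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            balanced_batch([np.arange(3), np.array([], int)], 10, rng)


class TestMLPForward:
    def test_zero_weights_uniform_probabilities(self, rng):
        arch = MLPArchitecture((8,), input_dim=4, output_dim=4)
        model = init_mlp(arch, rng)
        for w in model.weights:
            w[:] = 0.0
        probs = mlp_forward(model, np.zeros(4))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        arch = MLPArchitecture((16, 8), input_dim=36, output_dim=3)
        model = init_mlp(arch, rng)
        for _ in range(10):
            p = mlp_forward(model, rng.integers(0, 255, 36))
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)

    def test_toy_network_hand_computed(self, rng):
        """Two-pixel net checked against manual layer-by-layer arithmetic."""
        arch = MLPArchitecture((2,), input_dim=2, output_dim=2)
        model = init_mlp(arch, rng)
        model.weights[0][:] = [[1.0, -1.0], [0.5, 2.0]]
        model.biases[0][:] = [0.5, -1.0]
        model.weights[1][:] = [[1.0, 0.0], [-1.0, 2.0]]
        model.biases[1][:] = [0.0, 0.5]
        probs = mlp_forward(model, np.array([51.0, 102.0]))  # /255 -> .2, .4
        # hidden: relu([.2 + .2 + .5, -.2 + .8 - 1]) = [0.9, 0]
        # output logits: [0.9, 0.5]
        p0 = 1.0 / (1.0 + math.exp(-(0.9 - 0.5)))
        np.testing.assert_allclose(probs, [p0, 1.0 - p0], atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        model = init_mlp(MLPArchitecture((4,), input_dim=9, output_dim=2), rng)
        with pytest.raises(ValueError):
            mlp_forward(model, np.zeros(10))


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        arch = MLPArchitecture((5, 4), input_dim=6, output_dim=3)
        model = init_mlp(arch, rng)
        X = rng.integers(0, 255, (7, 6)).astype(float)
        y = rng.integers(0, 3, 7)
        _, gw, gb = loss_and_grads(model, X, y)
        eps = 1e-6
        for li in range(len(model.weights)):
            for idx in [(0, 0), (2, 1), (model.weights[li].shape[0] - 1,
                                         model.weights[li].shape[1] - 1)]:
                orig = model.weights[li][idx]
                model.weights[li][idx] = orig + eps
                lp, _, _ = loss_and_grads(model, X, y)
                model.weights[li][idx] = orig - eps
                lm, _, _ = loss_and_grads(model, X, y)
                model.weights[li][idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert gw[li][idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


@pytest.fixture(scope="module")
def small_data(config):
    rng = np.random.default_rng(21)
    return make_two_class_dataset(config, 150, rng)


class TestTrain:
    def test_zero_learning_rate_leaves_weights(self, small_data, rng):
        arch = MLPArchitecture((16,), input_dim=36 * 36, output_dim=2)
        model = init_mlp(arch, rng)
        before = [w.copy() for w in model.weights]
        train(model, small_data, TrainConfig(learning_rate=0.0, iterations=20,
                                             eval_interval=10))
        for b, w in zip(before, model.weights):
            assert np.array_equal(b, w)

    def test_reproducible_under_seed(self, small_data):
        results = []
        for _ in range(2):
            model = init_mlp(MLPArchitecture((16,), input_dim=1296, output_dim=2),
                             np.random.default_rng(7))
            train(model, small_data,
                  TrainConfig(learning_rate=1e-3, iterations=30,
                              eval_interval=10, seed=5))
            results.append([w.copy() for w in model.weights])
        for a, b in zip(*results):
            assert np.array_equal(a, b)

    def test_learns_separable_classes(self, small_data):
        model = init_mlp(MLPArchitecture((32,), input_dim=1296, output_dim=2),
                         np.random.default_rng(1))
        res = train(model, small_data,
                    TrainConfig(learning_rate=1e-3, iterations=600,
                                eval_interval=100, seed=2))
        assert not res.diverged
        assert res.val_accuracy[-1] > 0.8

    def test_smoothed_accuracy_window(self, small_data):
        model = init_mlp(MLPArchitecture((8,), input_dim=1296, output_dim=2),
                         np.random.default_rng(1))
        res = train(model, small_data,
                    TrainConfig(learning_rate=1e-4, iterations=100,
                                eval_interval=10))
        sm = res.smoothed_accuracy(window=5)
        assert sm.shape == res.val_accuracy.shape


class TestLRScreen:
    def test_planted_knee_recovered_within_one_grid_step(self):
        """Synthetic loss curve with a steep drop at 1e-4."""
        lrs = np.logspace(-6, -1, 11)
        losses = 0.7 - 0.5 / (1.0 + np.exp(-(np.log10(lrs) + 4.0) * 6.0))
        losses[lrs > 1e-2] = 2.0  # divergence at the top of the grid
        knee, degenerate = knee_from_curve(lrs, losses)
        assert not degenerate
        assert abs(math.log10(knee) - (-4.0)) <= 0.5 + 1e-9

    def test_flat_curve_degenerate(self):
        lrs = np.logspace(-6, -2, 9)
        knee, degenerate = knee_from_curve(lrs, np.full(9, 0.693))
        assert degenerate and knee is None

    def test_single_point_grid_returned_trivially(self, config):
        rng = np.random.default_rng(3)
        data = make_two_class_dataset(config, 40, rng)
        model = init_mlp(MLPArchitecture((8,), input_dim=1296, output_dim=2), rng)
        res = lr_screen(model, data, [1e-4], iters_per_lr=5)
        assert res.knee_lr == 1e-4 and not res.degenerate

    def test_screen_returns_loss_per_lr(self, config):
        rng = np.random.default_rng(3)
        data = make_two_class_dataset(config, 40, rng)
        model = init_mlp(MLPArchitecture((8,), input_dim=1296, output_dim=2), rng)
        res = lr_screen(model, data, [1e-5, 1e-3, 1e-1], iters_per_lr=10)
        assert isinstance(res, LRScreenResult)
        assert res.losses.shape == (3,)
        assert np.all(np.isfinite(res.losses) | (res.losses == np.inf))


class TestDoubletRules:
    @staticmethod
    def _truth(n_objects, nn_um):
        return GroundTruth(timestamp=0.0, n_objects=n_objects,
                           object_centroids=((10.0, 10.0),) * n_objects,
                           nearest_neighbor_um=nn_um, true_area_um2=25.0,
                           true_tilt_deg=5.0, fluorescence=100.0,
                           cell_class="A", in_avalanche=False)

    @pytest.mark.parametrize("n,nn,expected", [
        (1, 30.0, "single"),
        (1, 10.0, "doublet"),   # proximity rule: neighbour closer than 15 um
        (2, 0.0, "doublet"),
    ])
    def test_label_rule(self, n, nn, expected):
        assert doublet_label(self._truth(n, nn)) == expected

    def test_filter_threshold(self):
        p = [0.0, 0.29, 0.30, 0.31, 1.0]
        keep = doublet_filter(p)
        assert list(keep) == [True, True, True, False, False]

    def test_filter_threshold_one_keeps_all(self):
        assert doublet_filter([0.5, 0.99, 1.0], p_threshold=1.0).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            doublet_filter([1.2])
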