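"""Loss functions, boundary weights, augmentation, and the training loop."""

from dataclasses import replace

import numpy as np
import pytest

from leafletseg.core import ImageGrid, LeafletLabelMap
from leafletseg.encoding import ChannelStack
from leafletseg.network import ModelSpec, build_model
from leafletseg.training import (
    AugmentConfig,
    LossConfig,
    TrainConfig,
    augment_sample,
    boundary_weight_map,
    composite_loss,
    composite_loss_grad,
    one_hot,
    soft_dice_loss,
    train,
    weighted_ce_loss,
)


def _brute_boundary_weights(labels, cfg=LossConfig()):
    """Oracle: exhaustive boundary detection and distance computation."""
    shape = labels.shape
    boundary = []
    for v in np.ndindex(shape):
        for ax in range(3):
            for d in (-1, 1):
                w = list(v)
                w[ax] += d
                if 0 <= w[ax] < shape[ax] and labels[tuple(w)] != labels[v]:
                    boundary.append(v)
                    break
            else:
                continue
            break
    weights = np.full(shape, 1.0 / cfg.n_classes)
    if boundary:
        b = np.asarray(boundary, dtype=float)
        for v in np.ndindex(shape):
            if np.min(np.linalg.norm(b - np.asarray(v), axis=1)) < cfg.border_distance:
                weights[v] += cfg.border_weight
    return weights


class TestBoundaryWeights:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(5, 11, size=3))
        labels = (rng.random(shape) < 0.25).astype(np.uint8) * rng.integers(1, 4)
        got = boundary_weight_map(labels)
        np.testing.assert_array_equal(got, _brute_boundary_weights(labels))

    def test_far_voxel_gets_class_term_only(self):
        labels = np.zeros((16, 16, 16), dtype=np.uint8)
        labels[:2, :2, :2] = 1
        w = boundary_weight_map(labels)
        assert w[10, 10, 10] == pytest.approx(0.25)

    def test_boundary_voxel_gets_border_plus_class_term(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[:, :, :4] = 1
        w = boundary_weight_map(labels)
        assert w[4, 4, 3] == pytest.approx(50.25)

    def test_uniform_labels_have_no_boundary(self):
        w = boundary_weight_map(np.zeros((6, 6, 6), dtype=np.uint8))
        np.testing.assert_allclose(w, 0.25)

    def test_rebalancing_weights_from_inverse_frequencies(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[0, 0, :2] = 1
        labels[0, 1, :2] = 2
        labels[0, 2, :2] = 3
        cfg = replace(LossConfig(), use_class_rebalancing=True)
        w = boundary_weight_map(labels, cfg)
        counts = np.bincount(labels.ravel(), minlength=4).astype(float)
        inv = 1.0 / counts
        expected_far = (inv / inv.sum())[0]
        assert w[7, 7, 7] == pytest.approx(expected_far)


class TestLosses:
    def test_perfect_prediction_near_zero_dice(self, rng):
        labels = rng.integers(0, 4, (4, 4, 4)).astype(np.uint8)
        oh = one_hot(labels)
        assert soft_dice_loss(oh, oh) < 1e-4

    def test_uniform_probs_match_hand_formula(self, rng):
        labels = rng.integers(0, 4, (4, 4, 4)).astype(np.uint8)
        oh = one_hot(labels).astype(np.float64)
        probs = np.full_like(oh, 0.25)
        n = labels.size
        eps = 1e-5
        expected = 1.0 - np.mean(
            [
                (2 * 0.25 * (labels == c).sum() + eps)
                / (0.25 * n + (labels == c).sum() + eps)
                for c in range(4)
            ]
        )
        assert soft_dice_loss(probs, oh) == pytest.approx(expected, rel=1e-9)

    def test_disjoint_prediction_near_one(self):
        """When every class's predicted and true supports are disjoint the
        per-class overlap terms all vanish and the loss approaches 1."""
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[:2] = 1                    # gt uses classes 0 and 1
        wrong = np.full((4, 4, 4), 2, dtype=np.uint8)
        wrong[:2] = 3                     # prediction uses classes 2 and 3
        assert soft_dice_loss(one_hot(wrong), one_hot(labels)) > 0.999

    def test_uniform_probs_ce_is_log4_for_any_weights(self, rng):
        labels = rng.integers(0, 4, (4, 4, 4)).astype(np.uint8)
        probs = np.full((4, 4, 4, 4), 0.25)
        for _ in range(3):
            w = rng.random((4, 4, 4)) + 0.01
            assert weighted_ce_loss(probs, labels, w) == pytest.approx(np.log(4), rel=1e-9)

    def test_boundary_error_costs_more_than_interior_error(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[:, :, :4] = 1
        w = boundary_weight_map(labels)
        base = one_hot(labels) * 0.97 + 0.01

        def with_error_at(v):
            p = base.copy()
            p[:, v[0], v[1], v[2]] = [0.97 if labels[v] != 0 else 0.01] * 1 + [0.01, 0.01, 0.01]
            p[0, v[0], v[1], v[2]] = 0.97 if labels[v] == 1 else 0.01
            p[1, v[0], v[1], v[2]] = 0.01 if labels[v] == 1 else 0.97
            return weighted_ce_loss(p, labels, w)

        boundary_voxel = (4, 4, 3)  # label 1 voxel adjacent to the interface
        interior_voxel = (4, 4, 0)  # label 1 voxel far from it
        assert w[boundary_voxel] > w[interior_voxel]
        assert with_error_at(boundary_voxel) > with_error_at(interior_voxel)

    def test_all_zero_weights_rejected(self):
        labels = np.zeros((2, 2, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            weighted_ce_loss(np.full((4, 2, 2, 2), 0.25), labels, np.zeros((2, 2, 2)))

    def test_composite_combines_terms(self, rng):
        labels = rng.integers(0, 4, (4, 4, 4)).astype(np.uint8)
        probs = np.full((4, 4, 4, 4), 0.25)
        w = boundary_weight_map(labels)
        expected = soft_dice_loss(probs, one_hot(labels)) + 0.02 * np.log(4)
        assert composite_loss(probs, labels, weights=w) == pytest.approx(expected, rel=1e-9)

    def test_composite_nonnegative_and_zero_at_perfect(self, rng):
        labels = rng.integers(0, 4, (4, 4, 4)).astype(np.uint8)
        perfect = np.clip(one_hot(labels), 1e-7, 1.0)
        assert 0 <= composite_loss(perfect, labels) < 1e-3
        for _ in range(5):
            p = rng.random((4, 4, 4, 4))
            p /= p.sum(axis=0, keepdims=True)
            assert composite_loss(p, labels) >= 0


def test_composite_gradient_matches_finite_differences(rng):
    """Central-difference check of d(loss)/d(probs) on 4^3 cases, 1e-3 relative."""
    labels = rng.integers(0, 4, (4, 4, 4)).astype(np.uint8)
    probs = rng.uniform(0.05, 0.95, (4, 4, 4, 4))
    probs /= probs.sum(axis=0, keepdims=True)
    _, grad = composite_loss_grad(probs, labels)
    w = boundary_weight_map(labels)
    check = np.random.default_rng(0)
    for _ in range(25):
        idx = tuple(check.integers(s) for s in probs.shape)
        eps = 1e-6
        p1, p2 = probs.copy(), probs.copy()
        p1[idx] += eps
        p2[idx] -= eps
        fd = (composite_loss(p1, labels, weights=w) - composite_loss(p2, labels, weights=w)) / (2 * eps)
        assert abs(fd - grad[idx]) <= 1e-3 * max(1.0, abs(fd))


def _desk_sample(case, grid_shape=(48, 48, 48)):
    return case


class TestAugmentation:
    def test_seeded_draws_are_identical(self, desk_case):
        _, gt, _, stack = desk_case
        a = augment_sample(stack, gt, AugmentConfig(), seed=3)
        b = augment_sample(stack, gt, AugmentConfig(), seed=3)
        np.testing.assert_array_equal(a[0].channels, b[0].channels)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_zero_probability_is_identity(self, desk_case):
        _, gt, _, stack = desk_case
        out_stack, out_gt = augment_sample(stack, gt, replace(AugmentConfig(), probability=0.0), seed=1)
        np.testing.assert_allclose(out_stack.channels, stack.channels, atol=1e-6)
        np.testing.assert_array_equal(out_gt.labels, gt.labels)

    def test_rotation_preserves_labels_approximately(self, desk_case):
        """A pure rotation keeps the label set and roughly the voxel counts
        (nearest-neighbor resampling bound on the phantom)."""
        _, gt, _, stack = desk_case
        cfg = replace(AugmentConfig(), translation_voxels=0.0, scale=0.0, probability=1.0)
        _, out_gt = augment_sample(stack, gt, cfg, seed=11)
        assert set(np.unique(out_gt.labels)) <= {0, 1, 2, 3}
        for label in (1, 2, 3):
            n0 = (gt.labels == label).sum()
            n1 = (out_gt.labels == label).sum()
            assert abs(n1 - n0) <= 0.25 * n0


def _tiny_dataset(n_cases, rng, shape=(16, 16, 16)):
    grid = ImageGrid(shape=shape, spacing=(0.5,) * 3)
    out = []
    for _ in range(n_cases):
        labels = np.zeros(shape, dtype=np.uint8)
        c = rng.integers(5, 11, size=3)
        labels[c[0] - 3 : c[0] + 3, c[1] - 3 : c[1] + 3, c[2] - 2 : c[2] + 2] = rng.integers(1, 4)
        img = (labels > 0) * 0.8 + rng.random(shape) * 0.1
        stack = ChannelStack(
            channels=img[None].astype(np.float32), channel_roles=["frame:MS"], grid=grid
        )
        out.append((stack, LeafletLabelMap(labels=labels, grid=grid)))
    return out


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def run(self):
        rng = np.random.default_rng(0)
        dataset = _tiny_dataset(5, rng)
        model = build_model(ModelSpec(in_channels=1, base_filters=4, n_stages=2), seed=0)
        cfg = TrainConfig(seed=0, batch_size=2, lr_patience=1)
        model, history = train(model, dataset, cfg, LossConfig(), aug_cfg=None, max_epochs=8)
        return dataset, cfg, history

    def test_history_schema(self, run):
        _, _, history = run
        assert len(history) == 8
        assert {"epoch", "train_loss", "val_loss", "lr"} <= set(history[0])

    def test_best_validation_loss_is_monotone(self, run):
        _, _, history = run
        best = np.minimum.accumulate([h["val_loss"] for h in history])
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_lr_only_halves(self, run):
        _, _, history = run
        lrs = [h["lr"] for h in history]
        for a, b in zip(lrs, lrs[1:]):
            assert b == a or b == pytest.approx(a / 2)

    def test_seeded_rerun_identical(self, run):
        dataset, cfg, history = run
        model2 = build_model(ModelSpec(in_channels=1, base_filters=4, n_stages=2), seed=0)
        _, history2 = train(model2, dataset, cfg, LossConfig(), aug_cfg=None, max_epochs=8)
        assert [h["train_loss"] for h in history] == [h["train_loss"] for h in history2]
        assert [h["val_loss"] for h in history] == [h["val_loss"] for h in history2]

    def test_small_dataset_rejected(self, rng):
        model = build_model(ModelSpec(in_channels=1, base_filters=4, n_stages=2), seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            train(model, _tiny_dataset(1, rng), TrainConfig(), LossConfig())
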