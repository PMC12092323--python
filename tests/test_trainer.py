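"""Losses, ground-truth rendering, subdivision, augmentation, schedule, training."""

import numpy as np
import pytest

from rnadotseg import trainer
from rnadotseg.trainer import (
    AugmentConfig, LossConfig, OptimizerConfig, PhaseSpec, SchedulingError,
    apply_geometric, augment, bce_loss, default_schedule, denormalize_input,
    dice_loss, jaccard_loss, normalize_input, render_gt_mask, subdivide_patch,
    tversky_loss,
)
from rnadotseg.netarch import NetworkConfig, build_network


class TestGroundTruth:
    def test_interior_dot_renders_five_pixel_cross(self):
        m = render_gt_mask([(5, 5)], (11, 11))
        assert m.sum() == 5
        assert m[5, 5] == m[5, 4] == m[5, 6] == m[4, 5] == m[6, 5] == 1

    def test_corner_dot_clipped_to_three_pixels(self):
        m = render_gt_mask([(0, 0)], (8, 8))
        assert m.sum() == 3

    def test_empty_dot_list(self):
        assert render_gt_mask([], (4, 4)).sum() == 0

    def test_overlapping_crosses_take_union(self):
        m = render_gt_mask([(3, 3), (4, 3)], (8, 8))
        assert m.sum() == 8  # 10 pixels minus 2 shared

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            render_gt_mask([(9, 0)], (8, 8))


class TestLosses:
    def test_perfect_prediction_is_near_zero(self, rng):
        g = (rng.random((16, 16)) < 0.2).astype(float)
        assert tversky_loss(g, g) < 1e-5
        assert dice_loss(g, g) < 1e-5
        assert jaccard_loss(g, g) < 1e-5
        assert bce_loss(g, g) < 1e-5

    def test_inverted_prediction_approaches_one(self, rng):
        g = (rng.random((16, 16)) < 0.3).astype(float)
        assert tversky_loss(1.0 - g, g, smooth=1e-12) > 1 - 1e-6

    def test_tversky_hand_computed_case(self):
        pred = np.array([[1.0, 0.0], [0.0, 0.0]])
        gt = np.array([[1.0, 1.0], [0.0, 0.0]])
        # TP=1, FN=1, FP=0 -> 1 - 1/(1+0.6) = 0.375
        assert tversky_loss(pred, gt, alpha=0.6, smooth=0.0) == pytest.approx(0.375)

    def test_dice_equals_tversky_half(self, rng):
        for _ in range(100):
            p = rng.random((12, 12))
            g = (rng.random((12, 12)) < 0.3).astype(float)
            assert abs(dice_loss(p, g) - tversky_loss(p, g, alpha=0.5)) < 1e-6

    def test_jaccard_at_least_dice(self, rng):
        for _ in range(50):
            p = rng.random((10, 10))
            g = (rng.random((10, 10)) < 0.4).astype(float)
            assert jaccard_loss(p, g) >= dice_loss(p, g) - 1e-12

    def test_loss_monotone_in_corruption(self):
        g = np.zeros((12, 12))
        g[4:8, 4:8] = 1.0
        pos = np.argwhere(g == 1)
        losses = []
        for k in range(6):
            p = g.copy()
            for r, c in pos[:k]:
                p[r, c] = 0.0
            losses.append(tversky_loss(p, g, alpha=0.6))
        assert losses == sorted(losses)
        assert losses[0] < losses[-1]

    def test_all_negative_gt_zero_pred_dice_zero(self):
        g = np.zeros((8, 8))
        assert dice_loss(np.zeros((8, 8)), g) == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tversky_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_unknown_loss_kind_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(kind="focal")


class TestSubdivision:
    def test_eval_grid_on_480(self):
        img = np.zeros((480, 480, 3), dtype=np.uint8)
        tiles = subdivide_patch(img, [], "eval")
        assert len(tiles) == 9
        assert sorted({t.origin for t in tiles}) == [
            (x, y) for x in (0, 128, 256) for y in (0, 128, 256)]

    def test_dot_coordinates_shift_into_tile_frame(self):
        img = np.zeros((480, 480, 3), dtype=np.uint8)
        tiles = subdivide_patch(img, [(230, 230, "primary")], "eval")
        tile = next(t for t in tiles if t.origin == (128, 128))
        assert tile.dots == [(102, 102, "primary")]

    def test_dots_outside_tile_dropped(self):
        img = np.zeros((256, 256, 3), dtype=np.uint8)
        tiles = subdivide_patch(img, [(250, 250)], "eval", tile=224, stride=128)
        assert sum(len(t.dots) for t in tiles) == 1  # only the offset tile keeps it

    def test_train_mode_seeded_and_reproducible(self):
        img = np.zeros((300, 300, 3), dtype=np.uint8)
        a = subdivide_patch(img, [], "train", rng=np.random.default_rng(3), n_crops=4)
        b = subdivide_patch(img, [], "train", rng=np.random.default_rng(3), n_crops=4)
        assert [t.origin for t in a] == [t.origin for t in b]

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            subdivide_patch(np.zeros((100, 100, 3)), [], "eval")


class TestAugment:
    def test_hflip_involution(self, rng):
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        mask = (rng.random((16, 16)) < 0.2).astype(float)
        once_i, once_m = apply_geometric(img, mask, hflip=True)
        twice_i, twice_m = apply_geometric(once_i, once_m, hflip=True)
        np.testing.assert_array_equal(twice_i, img)
        np.testing.assert_array_equal(twice_m, mask)

    def test_flips_conserve_positive_count(self, rng):
        img = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        mask = (rng.random((16, 16)) < 0.2).astype(float)
        for kw in ({"hflip": True}, {"vflip": True}, {"hflip": True, "vflip": True}):
            _, m = apply_geometric(img, mask, **kw)
            assert m.sum() == mask.sum()

    def test_mask_stays_binary_under_rotation(self, rng):
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        mask = (rng.random((32, 32)) < 0.2).astype(float)
        _, m = augment(img, mask, rng, AugmentConfig())
        assert set(np.unique(m)) <= {0.0, 1.0}

    def test_rotation_bounded_by_config(self):
        with pytest.raises(ValueError):
            AugmentConfig(max_rotation_degrees=120)


class TestNormalization:
    def test_mean_image_maps_to_zero(self):
        img = np.rint(trainer.IMAGENET_MEAN_BGR * 255).astype(np.uint8)
        img = np.tile(img, (8, 8, 1))
        out = normalize_input(img)
        assert np.abs(out).max() < 0.02

    def test_roundtrip(self, rng):
        img = rng.integers(0, 255, (8, 8, 3)).astype(np.uint8)
        back = denormalize_input(normalize_input(img))
        np.testing.assert_allclose(back, img, atol=1e-9)

    def test_finite_for_extremes(self):
        for v in (0, 255):
            assert np.isfinite(normalize_input(np.full((4, 4, 3), v, np.uint8))).all()


class TestSchedule:
    def test_six_phase_curriculum(self):
        sched = default_schedule()
        rows = [(p.real_samples_per_epoch, p.generated_samples_per_epoch,
                 p.epochs, p.backbone_frozen) for p in sched]
        assert rows == [(460, 1071, 128, True), (460, 460, 128, False),
                        (460, 230, 128, False), (460, 115, 128, False),
                        (460, 58, 128, False), (460, 0, 1024, False)]
        assert sum(p.epochs for p in sched) == 1664
        assert [p.backbone_frozen for p in sched] == [True] + [False] * 5

    def test_phase_validation(self):
        with pytest.raises(ValueError):
            PhaseSpec(-1, 0, 1)
        with pytest.raises(ValueError):
            PhaseSpec(4, 0, 0)


class TestTrainLoop:
    def _schedule(self, epochs=1, frozen=False, generated=0):
        return [PhaseSpec(real_samples_per_epoch=4,
                          generated_samples_per_epoch=generated,
                          epochs=epochs, backbone_frozen=frozen)]

    def _model(self, seed=0):
        return build_network(NetworkConfig(backbone_size="tiny", input_size=32),
                             seed=seed)

    def test_smoke_one_epoch(self, small_patches):
        hist = trainer.train(self._model(), small_patches, [], self._schedule(),
                             seed=1, augment_config=None)
        assert len(hist) == 1
        assert np.isfinite(hist[0]["loss"])

    def test_frozen_phase_keeps_backbone_bit_identical(self, small_patches):
        model = self._model(seed=2)
        before = {k: p.data.copy() for k, p in model.backbone.named_parameters()}
        trainer.train(model, small_patches, [], self._schedule(frozen=True), seed=1,
                      augment_config=None)
        for k, p in model.backbone.named_parameters():
            np.testing.assert_array_equal(p.data, before[k])

    def test_seeded_runs_reproduce_loss_curves(self, small_patches):
        h1 = trainer.train(self._model(seed=4), small_patches, [],
                           self._schedule(epochs=2), seed=9)
        h2 = trainer.train(self._model(seed=4), small_patches, [],
                           self._schedule(epochs=2), seed=9)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_insufficient_generated_data_raises(self, small_patches):
        with pytest.raises(SchedulingError):
            trainer.train(self._model(), small_patches, [],
                          self._schedule(generated=5), seed=1)

    def test_generated_data_consumed(self, small_patches):
        hist = trainer.train(self._model(), small_patches, list(small_patches),
                             self._schedule(generated=2), seed=1,
                             augment_config=None)
        assert len(hist) == 1

    def test_validation_iou_recorded(self, small_patches):
        hist = trainer.train(self._model(), small_patches, [], self._schedule(),
                             seed=1, val_data=small_patches[:1],
                             augment_config=None)
        assert "val_iou" in hist[0]
        assert 0.0 <= hist[0]["val_iou"] <= 1.0


class TestOptimizerConfig:
    def test_defaults_match_study_settings(self):
        cfg = OptimizerConfig()
        assert cfg.learning_rate == 0.005
        assert cfg.rho == 0.975
        assert cfg.batch_size == 4

    def test_positive_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(learning_rate=0)
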