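"""Patch extraction, Dice loss, U-Net mechanics, schedule, prediction."""

import numpy as np
import pytest

from cardioseg.bbox import BoundingBox
from cardioseg.core import ImagingError, LABEL_PRIORITY, LabelMap, STRUCTURE_CODES, Volume
from cardioseg.segnet import (
    PatchSpec,
    TrainConfig,
    UNet3D,
    axis_starts,
    conv_parameter_count,
    desk_profile,
    dice_loss,
    extract_patches,
    lr_at_epoch,
    predict,
    train,
)


class TestPatchExtraction:
    def test_single_tile_when_length_equals_patch(self):
        assert axis_starts(64, 64, 32) == [0]

    def test_start_enumeration_matches_count_formula(self):
        # L=160, p=64, s=32 -> starts {0, 32, 64, 96}
        starts = axis_starts(160, 64, 32)
        assert starts == [0, 32, 64, 96]
        assert len(starts) == (160 - 64) // 32 + 1
        # non-flush case gets a clamped final start
        assert axis_starts(150, 64, 32) == [0, 32, 64, 86]

    @pytest.mark.parametrize("shape", [(16, 16, 16), (20, 27, 33), (8, 40, 16)])
    def test_every_voxel_covered(self, shape, rng):
        spec = PatchSpec((16, 16, 16), (8, 12, 16))
        vol = Volume(rng.normal(size=shape))
        lab = LabelMap(np.zeros(shape, dtype=np.int16))
        covered = np.zeros([max(s, p) for s, p in zip(shape, spec.size)], dtype=int)
        for _img, _tgt, pos in extract_patches(vol, lab, spec):
            sl = tuple(slice(p, p + q) for p, q in zip(pos, spec.size))
            covered[sl] += 1
        assert (covered > 0).all()

    def test_invalid_stride_rejected(self):
        with pytest.raises(ImagingError):
            PatchSpec((16, 16, 16), (32, 8, 8))


class TestDiceLoss:
    def test_perfect_binary_prediction_zero_loss(self, rng):
        tgt = (rng.random((5, 6, 6, 6)) > 0.5).astype(float)
        loss, grad = dice_loss(tgt, tgt, eps=1.0)
        assert loss == pytest.approx(0.0)

    def test_empty_vs_empty_convention(self):
        z = np.zeros((5, 4, 4, 4))
        loss, _ = dice_loss(z, z, eps=1.0)
        assert loss == pytest.approx(0.0)

    def test_hand_computed_half_loss(self):
        # one 8-voxel channel, 4 target voxels, uniform prediction 0.5:
        # 1 - 2*(0.5*4) / (0.5*8 + 4) = 0.5 in the eps -> 0 limit
        pred = np.full((1, 2, 2, 2), 0.5)
        tgt = np.zeros((1, 2, 2, 2))
        tgt[0, 0] = 1.0
        loss, _ = dice_loss(pred, tgt, eps=1e-12)
        assert loss == pytest.approx(0.5, abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.random((2, 3, 3, 3)) * 0.8 + 0.1
        tgt = (rng.random((2, 3, 3, 3)) > 0.5).astype(float)
        loss, grad = dice_loss(pred, tgt, eps=1.0)
        eps = 1e-7
        for idx in [(0, 0, 0, 0), (1, 2, 1, 0), (0, 1, 2, 2)]:
            p2 = pred.copy()
            p2[idx] += eps
            l2, _ = dice_loss(p2, tgt, eps=1.0)
            assert (l2 - loss) / eps == pytest.approx(grad[idx], rel=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ImagingError):
            dice_loss(np.zeros((5, 2, 2, 2)), np.zeros((5, 2, 2, 4)))

    def test_loss_bounded_zero_one(self, rng):
        for _ in range(5):
            pred = rng.random((5, 4, 4, 4))
            tgt = (rng.random((5, 4, 4, 4)) > 0.7).astype(float)
            loss, _ = dice_loss(pred, tgt, eps=1.0)
            assert 0.0 <= loss <= 1.0


class TestUNet:
    def test_forward_shape_and_sigmoid_range(self):
        model = UNet3D(TrainConfig(base_features=4, groups=2, levels=2))
        out = model.forward(np.zeros((1, 8, 8, 8)))
        assert out.shape == (5, 8, 8, 8)
        assert np.isfinite(out).all()
        assert (out > 0).all() and (out < 1).all()

    def test_indivisible_groups_rejected(self):
        with pytest.raises(ImagingError):
            UNet3D(TrainConfig(base_features=6, groups=4))

    def test_parameter_count_matches_analytic_formula(self):
        cfg = TrainConfig(base_features=4, groups=2, levels=2)
        model = UNet3D(cfg)
        f = [4, 8]

        def block(cin, cout):
            return (
                conv_parameter_count(cin, cout)
                + conv_parameter_count(cout, cout)
                + 4 * cout  # two group norms
            )

        expected = (
            block(1, f[0]) + block(f[0], f[1])  # encoder
            + block(f[1] + f[0], f[0])  # decoder
            + conv_parameter_count(f[0], 5, k=1)  # head
        )
        assert model.parameter_count() == expected

    def test_doubling_features_quadruples_conv_params(self):
        small = UNet3D(TrainConfig(base_features=4, groups=2, levels=2))
        big = UNet3D(TrainConfig(base_features=8, groups=2, levels=2))
        # conv weights dominate; ratio approaches 4 from below
        assert 3.0 < big.parameter_count() / small.parameter_count() <= 4.0

    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = TrainConfig(base_features=4, groups=2, levels=2, seed=5)
        model = UNet3D(cfg)
        x = rng.normal(size=(1, 8, 8, 8))
        before = model.forward(x)
        model.save(tmp_path / "m")
        loaded = UNet3D.load(tmp_path / "m")
        np.testing.assert_allclose(loaded.forward(x), before, atol=1e-12)


class TestSchedule:
    def test_lr_drops_by_gamma_at_milestones(self):
        cfg = TrainConfig(lr=1e-4, gamma=0.1, milestones=(50, 75))
        assert lr_at_epoch(cfg, 0) == 1e-4
        assert lr_at_epoch(cfg, 50) == pytest.approx(1e-5)
        assert lr_at_epoch(cfg, 75) == pytest.approx(1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ImagingError):
            TrainConfig(gamma=1.5)
        with pytest.raises(ImagingError):
            TrainConfig(milestones=(20, 10))


class TestTraining:
    def test_same_seed_reproduces_first_epoch_loss(self, coarse_case):
        from cardioseg.bbox import detect_bounding_box

        box = detect_bounding_box(coarse_case.volume)
        cfg = desk_profile(epochs=1, seed=3)
        spec = PatchSpec((16, 32, 32), (16, 32, 32))
        cases = [(coarse_case.volume, coarse_case.label, box)]
        _, h1 = train(cases, cfg, spec)
        _, h2 = train(cases, cfg, spec)
        assert abs(h1[0].mean_loss - h2[0].mean_loss) < 1e-5

    def test_history_reflects_schedule(self, coarse_case):
        from cardioseg.bbox import detect_bounding_box

        box = detect_bounding_box(coarse_case.volume)
        cfg = desk_profile(epochs=3, milestones=(1, 2), lr=1e-2, gamma=0.1)
        spec = PatchSpec((16, 32, 32), (16, 32, 32))
        _, hist = train([(coarse_case.volume, coarse_case.label, box)], cfg, spec)
        assert hist[0].lr == pytest.approx(1e-2)
        assert hist[1].lr == pytest.approx(1e-3)
        assert hist[2].lr == pytest.approx(1e-4)

    def test_empty_cases_rejected(self):
        with pytest.raises(ImagingError):
            train([], desk_profile(), PatchSpec((16, 16, 16), (16, 16, 16)))


class TestPredict:
    def _trained_toy(self, coarse_case):
        from cardioseg.bbox import detect_bounding_box

        box = detect_bounding_box(coarse_case.volume)
        cfg = desk_profile(max_iterations=5, epochs=5)
        spec = PatchSpec((16, 32, 32), (16, 32, 32))
        model, _ = train([(coarse_case.volume, coarse_case.label, box)], cfg, spec)
        return model, box, spec

    def test_subthreshold_probabilities_give_background(self, coarse_case):
        model, box, spec = self._trained_toy(coarse_case)
        out = predict(model, coarse_case.volume, box, spec, threshold=1.0)
        assert (out.data == 0).all()

    def test_priority_combination_rule(self):
        # a voxel positive in LV and LVM channels takes LV (earlier priority)
        probs = np.zeros((5, 2, 2, 2))
        probs[LABEL_PRIORITY.index("LV")] = 0.9
        probs[LABEL_PRIORITY.index("LVM")] = 0.8
        out = np.zeros((2, 2, 2), dtype=np.int16)
        for s in LABEL_PRIORITY:
            ch = LABEL_PRIORITY.index(s)
            m = (probs[ch] > 0.5) & (out == 0)
            out[m] = STRUCTURE_CODES[s]
        assert (out == STRUCTURE_CODES["LV"]).all()

    def test_non_overlapping_patches_match_loop_oracle(self, coarse_case):
        from cardioseg.bbox import crop as crop_fn
        from cardioseg.segnet.training import _pad_to, axis_starts, normalize_intensity

        model, _box, _ = self._trained_toy(coarse_case)
        # stride == patch and divisible extents: a truly non-overlapping grid
        box = BoundingBox((8, 8, 0), (24, 24, 32))
        spec = PatchSpec((8, 8, 8), (8, 8, 8))
        out = predict(model, coarse_case.volume, box, spec)
        vcrop = crop_fn(coarse_case.volume, box)
        img = _pad_to(
            normalize_intensity(vcrop.data.astype(np.float64), model.config.clip_window),
            spec.size,
        )
        oracle = np.zeros((5, *img.shape))
        for i in axis_starts(img.shape[0], 8, 8):
            for j in axis_starts(img.shape[1], 8, 8):
                for k in axis_starts(img.shape[2], 8, 8):
                    sl = (slice(i, i + 8), slice(j, j + 8), slice(k, k + 8))
                    oracle[(slice(None),) + sl] = model.forward(img[sl][None])
        labels = np.zeros(vcrop.shape, dtype=np.int16)
        probs = oracle[:, : vcrop.shape[0], : vcrop.shape[1], : vcrop.shape[2]]
        for s in LABEL_PRIORITY:
            ch = LABEL_PRIORITY.index(s)
            m = (probs[ch] > 0.5) & (labels == 0)
            labels[m] = STRUCTURE_CODES[s]
        np.testing.assert_array_equal(out.data[box.slices()], labels)

    def test_bad_priority_rejected(self, coarse_case):
        model, box, spec = self._trained_toy(coarse_case)
        with pytest.raises(ImagingError):
            predict(model, coarse_case.volume, box, spec, priority=("LV", "LV", "RV", "RA", "LVM"))
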