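"""Quasi-3D stacks, augmentation, U-Net contracts, Dice loss, training loop."""

import numpy as np
import pytest

from ivoiseg.core import ImageVolume
from ivoiseg.nn import dice_loss, dice_loss_and_grad_logits
from ivoiseg.phantom import cpu_preset, generate_cohort
from ivoiseg.quasi3d import (
    IVOI,
    MASK,
    TrainConfig,
    UNet,
    augment,
    build_unet,
    load_checkpoint,
    make_stacks,
    predict,
    save_checkpoint,
    train,
)

SP = (0.8, 0.3125, 0.3125)


class TestMakeStacks:
    def test_seventy_slices_give_seventy_stacks(self, rng):
        vol = rng.random((70, 128, 128)).astype(np.float32)
        stacks = make_stacks(vol, channels=3, in_size=128)
        assert len(stacks) == 70
        assert all(s.pixels.shape == (128, 128, 3) for s in stacks)

    def test_edge_slices_replicate_border(self, rng):
        vol = rng.random((5, 8, 8)).astype(np.float32)
        stacks = make_stacks(vol)
        np.testing.assert_array_equal(stacks[0].pixels[..., 0], vol[0])
        np.testing.assert_array_equal(stacks[0].pixels[..., 1], vol[0])
        np.testing.assert_array_equal(stacks[0].pixels[..., 2], vol[1])
        np.testing.assert_array_equal(stacks[-1].pixels[..., 2], vol[4])

    def test_middle_channel_is_center_slice(self, rng):
        vol = rng.random((7, 8, 8)).astype(np.float32)
        for z, s in enumerate(make_stacks(vol)):
            np.testing.assert_array_equal(s.pixels[..., 1], vol[z])

    def test_single_slice_volume_replicates_everywhere(self, rng):
        vol = rng.random((1, 8, 8)).astype(np.float32)
        (stack,) = make_stacks(vol)
        assert np.array_equal(stack.pixels[..., 0], stack.pixels[..., 1])
        assert np.array_equal(stack.pixels[..., 1], stack.pixels[..., 2])

    def test_single_channel_ablation(self, rng):
        vol = rng.random((4, 8, 8)).astype(np.float32)
        stacks = make_stacks(vol, channels=1)
        assert stacks[0].pixels.shape == (8, 8, 1)

    def test_in_plane_resampling(self, rng):
        vol = rng.random((3, 16, 16)).astype(np.float32)
        labels = rng.integers(0, 6, (3, 16, 16))
        stacks = make_stacks(vol, labels, in_size=8)
        assert stacks[0].pixels.shape == (8, 8, 3)
        assert stacks[0].target.shape == (8, 8)
        assert set(np.unique(stacks[0].target)) <= set(range(6))


class TestAugment:
    def _stack(self, rng):
        return make_stacks(
            rng.random((3, 16, 16)).astype(np.float32), rng.integers(0, 2, (3, 16, 16))
        )[1]

    def test_zero_ranges_identity(self, rng):
        cfg = TrainConfig(in_size=16, levels=2, aug_shift_frac=0, aug_rot_deg=0, aug_shear_deg=0)
        s = self._stack(rng)
        out = augment(s, cfg, seed=1)
        np.testing.assert_array_equal(out.pixels, s.pixels)

    def test_same_seed_same_output(self, rng):
        cfg = TrainConfig(in_size=16, levels=2, aug_shift_frac=0.1, aug_rot_deg=15, aug_shear_deg=5)
        s = self._stack(rng)
        a = augment(s, cfg, seed=42)
        b = augment(s, cfg, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.target, b.target)

    def test_quarter_turn_matches_coordinate_rotation_oracle(self, rng):
        """An exact 90-degree rotation is a pixel permutation; the resampled
        image must equal the brute-force coordinate-rotation oracle."""
        cfg = TrainConfig(in_size=16, levels=2, aug_rot_deg=90.0, aug_shift_frac=0, aug_shear_deg=0)
        img = rng.random((16, 16, 3)).astype(np.float32)
        target = rng.integers(0, 6, (16, 16)).astype(np.uint8)
        stack_cls = type(make_stacks(np.zeros((1, 16, 16), np.float32))[0])
        stack = stack_cls(pixels=img, center_index=0, subject_id="s", target=target)
        out = augment(stack, cfg, seed=0, params=(90.0, 0.0, 0.0, 0.0))
        h = 16
        expected = np.zeros_like(img)
        expected_t = np.zeros_like(target)
        # pull convention: out[i, j] reads in at rot(+90) @ (i - c, j - c) + c
        for i in range(h):
            for j in range(h):
                src_i = -(j - (h - 1) / 2) + (h - 1) / 2
                src_j = (i - (h - 1) / 2) + (h - 1) / 2
                expected[i, j] = img[round(src_i), round(src_j)]
                expected_t[i, j] = target[round(src_i), round(src_j)]
        # border pixels pull from coordinates an epsilon outside the grid
        # (cos 90deg is not exactly 0 in floats), so compare the interior
        core = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(out.pixels[core], expected[core], atol=1e-5)
        np.testing.assert_array_equal(out.target[core], expected_t[core])


class TestUNet:
    def test_mask_head_shape_and_range(self, rng):
        cfg = TrainConfig(levels=3, base_channels=8, in_size=64)
        net = build_unet(cfg, MASK)
        x = rng.standard_normal((2, 64, 64, 3)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (2, 64, 64, 1)
        assert p.min() >= 0 and p.max() <= 1

    def test_ivoi_head_softmax_sums_to_one(self, rng):
        cfg = TrainConfig(levels=3, base_channels=8, in_size=64)
        net = build_unet(cfg, IVOI)
        # randomize the head so the softmax is non-trivial
        r = np.random.default_rng(0)
        for p in net.head.params():
            p.val[...] = r.standard_normal(p.val.shape).astype(np.float32)
        x = rng.standard_normal((1, 64, 64, 3)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (1, 64, 64, 6)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_parameter_count_matches_layer_tally(self):
        """Parameter count equals the closed-form conv tally k*k*cin*cout + cout."""

        def tally(levels, c, channels, out_c):
            total = 0

            def conv(k, ci, co):
                return k * k * ci * co + co

            cin = channels
            enc = []
            for lvl in range(levels - 1):
                co = c * 2**lvl
                total_lvl = conv(3, cin, co) + conv(3, co, co)
                enc.append(co)
                total = total + total_lvl
                cin = co
            cb = c * 2 ** (levels - 1)
            total += conv(3, cin, cb) + conv(3, cb, cb)
            cur = cb
            for co in reversed(enc):
                total += 2 * 2 * cur * co + co  # deconv
                total += conv(3, 2 * co, co) + conv(3, co, co)
                cur = co
            total += conv(1, cur, out_c)
            return total

        cfg1 = TrainConfig(levels=3, base_channels=8, in_size=64)
        cfg2 = TrainConfig(levels=3, base_channels=16, in_size=64)
        n1 = build_unet(cfg1, MASK).n_params()
        n2 = build_unet(cfg2, MASK).n_params()
        assert n1 == tally(3, 8, 3, 1)
        assert n2 == tally(3, 16, 3, 1)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(levels=5, in_size=24)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        g = np.zeros((8, 8)); g[2:5, 2:5] = 1
        assert dice_loss(g.astype(float), g) <= 1.0 / (2 * 9 + 1)

    def test_half_probability_half_target(self):
        # p = 0.5 on N pixels, target has N/2 positives: soft Dice -> 0.5
        n = 10000
        pred = np.full(n, 0.5)
        target = np.zeros(n); target[: n // 2] = 1
        assert dice_loss(pred, target, eps=1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_empty_empty_is_lossless(self):
        assert dice_loss(np.zeros((4, 4)), np.zeros((4, 4))) == 0.0

    def test_out_of_range_pred_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.full((2, 2), 1.2), np.ones((2, 2)))

    def test_loss_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            pred = rng.random((6, 6))
            target = rng.integers(0, 2, (6, 6))
            assert 0.0 <= dice_loss(pred, target) <= 1.0
        for _ in range(10):
            logits = rng.standard_normal((2, 6, 6, 6))
            target = rng.integers(0, 6, (2, 6, 6))
            loss, _ = dice_loss_and_grad_logits(logits, target, IVOI)
            assert 0.0 <= loss <= 1.0

    def test_gradient_matches_finite_differences(self):
        """Backprop through the full net agrees with a numerical directional
        derivative (float64, random head)."""
        cfg = TrainConfig(levels=3, base_channels=2, in_size=8)
        rng = np.random.default_rng(0)
        for task, target in (
            (MASK, (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)),
            (IVOI, rng.integers(0, 6, (2, 8, 8))),
        ):
            net = UNet(cfg, task=task, rng=np.random.default_rng(1), dtype=np.float64)
            r = np.random.default_rng(2)
            for p in net.head.params():
                p.val[...] = r.standard_normal(p.val.shape) * 0.1
            x = rng.standard_normal((2, 8, 8, 3))
            _, dl = dice_loss_and_grad_logits(net.forward(x), target, task)
            for p in net.params():
                p.grad[...] = 0
            net.backward(dl)
            dirs = [np.random.default_rng(5).standard_normal(p.val.shape) for p in net.params()]
            analytic = sum(float((d * p.grad).sum()) for d, p in zip(dirs, net.params()))
            h = 1e-6
            for d, p in zip(dirs, net.params()):
                p.val += h * d
            lp = dice_loss_and_grad_logits(net.forward(x), target, task)[0]
            for d, p in zip(dirs, net.params()):
                p.val -= 2 * h * d
            lm = dice_loss_and_grad_logits(net.forward(x), target, task)[0]
            numeric = (lp - lm) / (2 * h)
            assert analytic == pytest.approx(numeric, rel=1e-6)


@pytest.fixture(scope="module")
def toy_cohort():
    spec = cpu_preset(grid_shape=(8, 32, 32), spacing_mm=(0.8, 0.625, 0.625), seed=3)
    return generate_cohort(spec, n_mice=2)


def _toy_config(**kw):
    base = dict(levels=2, base_channels=4, in_size=32, epochs=3, seed=5,
                aug_shift_frac=0, aug_rot_deg=0, aug_shear_deg=0)
    base.update(kw)
    return TrainConfig(**base)


class TestTraining:
    def test_loss_decreases_on_toy_cohort(self, toy_cohort):
        # a few dozen optimizer steps need a workable step size to show a
        # trend, so the smoke test raises the (configurable) learning rate
        model, hist = train(toy_cohort, MASK, _toy_config(epochs=5, learning_rate=1e-2))
        assert hist.mean_dice_loss.iloc[-1] < hist.mean_dice_loss.iloc[0]

    def test_2d_ablation_channel_config_trains(self, toy_cohort):
        model, hist = train(toy_cohort, MASK, _toy_config(channels=1, epochs=1))
        assert len(hist) == 1

    def test_training_is_deterministic(self, toy_cohort):
        _, h1 = train(toy_cohort, MASK, _toy_config(epochs=2))
        _, h2 = train(toy_cohort, MASK, _toy_config(epochs=2))
        assert h1.mean_dice_loss.tolist() == h2.mean_dice_loss.tolist()

    def test_subject_order_irrelevant_under_fixed_seed(self, toy_cohort):
        _, h1 = train(toy_cohort, MASK, _toy_config(epochs=1))
        _, h2 = train(list(reversed(toy_cohort)), MASK, _toy_config(epochs=1))
        # stacks are reshuffled by the seeded permutation, so the training
        # set (not its order) determines the epoch loss trajectory length
        assert len(h1) == len(h2)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            train([], MASK, _toy_config())

    def test_predict_shapes_and_range(self, toy_cohort):
        model, _ = train(toy_cohort, MASK, _toy_config(epochs=1))
        rec = toy_cohort[0]
        prob = predict(rec.mr, model)
        assert prob.shape == rec.mr.shape
        assert prob.min() >= 0 and prob.max() <= 1

    def test_prediction_is_slicewise(self, toy_cohort):
        """Volume prediction equals concatenated per-slice stack predictions."""
        model, _ = train(toy_cohort, MASK, _toy_config(epochs=1))
        rec = toy_cohort[0]
        full = predict(rec.mr, model)
        half_a = predict(ImageVolume(rec.mr.data, rec.mr.spacing_mm), model, batch_size=1)
        np.testing.assert_allclose(full, half_a, atol=1e-6)

    def test_ivoi_task_trains_and_predicts_six_channels(self, toy_cohort):
        model, _ = train(toy_cohort, IVOI, _toy_config(epochs=1))
        prob = predict(toy_cohort[0].mr, model)
        assert prob.shape == (*toy_cohort[0].mr.shape, 6)

    def test_checkpoint_roundtrip(self, toy_cohort, tmp_path):
        model, hist = train(toy_cohort, MASK, _toy_config(epochs=1))
        path = save_checkpoint(model, tmp_path / "m.npz", hist)
        back = load_checkpoint(path)
        rec = toy_cohort[0]
        np.testing.assert_allclose(predict(rec.mr, model), predict(rec.mr, back), atol=0)
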