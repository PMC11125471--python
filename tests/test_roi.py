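"""Nested U-Net: architecture, loss, patches, augmentation, training, boundaries."""

import dataclasses

import numpy as np
import pytest

from octexan import nn
from octexan.roi import (
    AugmentConfig,
    NoRoiError,
    RoiConfigError,
    UnetPPConfig,
    _loss_and_grad,
    augment,
    bce_dice_loss,
    boundaries_from_mask,
    build_model,
    extract_patches,
    load_model,
    predict_roi,
    save_model,
    train,
)
from octexan.synthetic import SceneConfig, generate_scene


def scalar_loss_oracle(y, p, eps=1e-7):
    """Independent scalar-loop evaluation of BCE + Dice."""
    y = np.asarray(y, float).ravel()
    p = np.clip(np.asarray(p, float).ravel(), eps, 1 - eps)
    bce = 0.0
    sy = sp = syp = 0.0
    for yi, pi in zip(y, p):
        bce += -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
        sy += yi
        sp += pi
        syp += yi * pi
    bce /= len(y)
    dice = 1.0 - 2.0 * syp / (sy + sp) if (sy + sp) > 0 else 0.0
    return bce + dice


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_dice_loss(np.ones((4, 4)), np.ones((4, 4))) < 1e-5

    def test_single_pixel_closed_form(self):
        got = bce_dice_loss(np.array([[1.0]]), np.array([[0.5]]))
        assert got == pytest.approx(np.log(2) + 1.0 / 3.0, abs=1e-9)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = (rng.random((4, 4)) > 0.5).astype(float)
            p = rng.random((4, 4))
            assert bce_dice_loss(y, p) == pytest.approx(scalar_loss_oracle(y, p), rel=1e-12)

    def test_extreme_probabilities_finite(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.0, 1.0]])
        assert np.isfinite(bce_dice_loss(y, p))


class TestArchitecture:
    def test_forward_shape_and_range(self):
        cfg = UnetPPConfig(base_filters=8, patch_size=64)
        model = build_model(cfg)
        out = nn.sigmoid(model.forward(np.random.default_rng(0).random((1, 1, 64, 64))))
        assert out.shape == (1, 1, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_zero_input_gives_constant_map(self):
        model = build_model(UnetPPConfig(base_filters=4, patch_size=32))
        out = model.forward(np.zeros((1, 1, 32, 32)))
        assert np.allclose(out, out.ravel()[0])

    def test_nested_net_has_more_parameters_than_plain_unet(self):
        nested = nn.UNetPP(depth=4, base_filters=8)
        plain = nn.PlainUNet(depth=4, base_filters=8)
        assert nested.n_parameters() > plain.n_parameters()

    def test_patch_size_depth_mismatch_rejected(self):
        with pytest.raises(RoiConfigError):
            build_model(UnetPPConfig(base_filters=4, patch_size=30))

    def test_gradients_match_finite_differences(self):
        model = nn.UNetPP(depth=2, base_filters=3, batch_norm=False, rng_seed=1)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        y = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)

        def loss_only():
            p = nn.sigmoid(model.forward(x, train=True)).astype(float)
            n = p.shape[0]
            pc = np.clip(p, 1e-7, 1 - 1e-7)
            bce = float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))
            dts = [1 - 2 * float((y[i] * p[i]).sum()) / (float(y[i].sum()) + float(p[i].sum()) + 1e-7)
                   for i in range(n)]
            return bce + float(np.mean(dts))

        _loss_and_grad(model, x, y)
        params = model.params()
        check = np.random.default_rng(3)
        for pi in [0, len(params) // 2, len(params) - 1]:
            p = params[pi]
            idx = tuple(check.integers(0, s) for s in p.value.shape)
            g_an = float(p.grad[idx])
            h = 1e-2
            old = p.value[idx]
            p.value[idx] = old + h
            lp = loss_only()
            p.value[idx] = old - h
            lm = loss_only()
            p.value[idx] = old
            g_num = (lp - lm) / (2 * h)
            assert g_an == pytest.approx(g_num, abs=max(5e-3, 0.05 * abs(g_num)))


class TestPatchesAndAugment:
    def test_full_image_patch_is_identity(self):
        img = np.random.default_rng(1).random((64, 64))
        cfg = UnetPPConfig(base_filters=4, patch_size=64, patches_per_image=5)
        patches = extract_patches(img, img > 0.5, cfg)
        assert len(patches) == 5
        for p, m in patches:
            assert np.array_equal(p, img)

    def test_patch_count_and_determinism(self):
        img = np.random.default_rng(2).random((128, 200))
        cfg = UnetPPConfig(base_filters=4, patch_size=64, patches_per_image=300, rng_seed=5)
        a = extract_patches(img, img > 0.5, cfg)
        b = extract_patches(img, img > 0.5, cfg)
        assert len(a) == 300
        for (pa, _), (pb, _) in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_too_small_image_rejected(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=64)
        with pytest.raises(RoiConfigError):
            extract_patches(np.zeros((32, 128)), np.zeros((32, 128)), cfg)

    def test_disabled_transforms_identity(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=32, augmentation=AugmentConfig(
            rotation_deg=0.0, zoom_range=(1.0, 1.0), distortion_magnitude_range=(0.0, 0.0),
            hflip=False))
        rng = np.random.default_rng(0)
        img = np.random.default_rng(1).random((32, 32))
        msk = (img > 0.5).astype(float)
        out_i, out_m = augment(img, msk, cfg, rng)
        assert np.allclose(out_i, img, atol=1e-6)
        assert np.array_equal(out_m, msk)

    def test_hflip_is_involution(self):
        img = np.random.default_rng(1).random((16, 16))
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_mask_stays_binary(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=32)
        rng = np.random.default_rng(7)
        img = np.random.default_rng(1).random((32, 32))
        msk = (img > 0.5).astype(float)
        for _ in range(10):
            _, out_m = augment(img, msk, cfg, rng)
            assert set(np.unique(out_m)) <= {0.0, 1.0}


def _tiny_dataset(n=8, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cfg = SceneConfig(image_height=96, image_width=128, rpe_row=72,
                          ilm=dataclasses.replace(SceneConfig().ilm, baseline_row=30.0,
                                                  fovea_depth=8.0, wing_amplitude=5.0),
                          n_exan_blobs=2, n_distractor_blobs=0, n_cysts=0,
                          rng_seed=int(rng.integers(0, 2**31 - 1)))
        scene = generate_scene(cfg)
        out.append((scene.image, scene.roi_mask.astype(float)))
    return out


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=32, patches_per_image=4,
                           epochs=3, learning_rate=1e-3, rng_seed=2)
        data = _tiny_dataset()
        m1, h1 = train(build_model(cfg), data, cfg)
        assert h1["train_loss"][-1] < h1["train_loss"][0]
        m2, h2 = train(build_model(cfg), data, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_empty_dataset_rejected(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=32)
        with pytest.raises(RoiConfigError):
            train(build_model(cfg), [], cfg)

    def test_model_roundtrips_through_file(self, tmp_path):
        cfg = UnetPPConfig(base_filters=4, patch_size=32, epochs=1, patches_per_image=2)
        model = build_model(cfg)
        x = np.random.default_rng(0).random((1, 1, 32, 32))
        before = model.forward(x)
        save_model(model, cfg, tmp_path / "m.npz")
        loaded, cfg2 = load_model(tmp_path / "m.npz")
        assert cfg2 == cfg
        assert np.array_equal(loaded.forward(x), before)


class TestPredictAndBoundaries:
    def test_constant_low_probability_gives_empty_mask(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=32, output_threshold=0.5)
        model = build_model(cfg)  # untrained: sigmoid(0) = 0.5 everywhere -> not > 0.5
        prob, mask = predict_roi(model, np.zeros((64, 64)), cfg)
        assert prob.shape == (64, 64)
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        assert not mask.any()
        with pytest.raises(NoRoiError):
            boundaries_from_mask(mask)

    def test_tiling_covers_nondivisible_sizes(self):
        cfg = UnetPPConfig(base_filters=4, patch_size=32)
        model = build_model(cfg)
        prob, mask = predict_roi(model, np.random.default_rng(0).random((70, 101)), cfg)
        assert prob.shape == (70, 101)
        assert np.isfinite(prob).all()

    def test_rectangle_mask_boundaries(self):
        mask = np.zeros((40, 30), dtype=bool)
        mask[10:21, :] = True
        lb = boundaries_from_mask(mask)
        assert np.all(lb.ilm == 10) and np.all(lb.rpe == 20)

    def test_single_column_mask(self):
        mask = np.zeros((20, 10), dtype=bool)
        mask[5:9, 3] = True
        lb = boundaries_from_mask(mask)
        assert lb.ilm[3] == 5 and lb.rpe[3] == 8
        assert np.isnan(lb.ilm[0]) and np.isnan(lb.rpe[9])

    def test_generator_mask_recovers_generator_curves(self):
        scene = generate_scene(SceneConfig(rng_seed=9))
        lb = boundaries_from_mask(scene.roi_mask)
        assert np.abs(lb.ilm - scene.ilm).max() <= 1.0
        assert np.abs(lb.rpe - scene.rpe).max() <= 1.0
        assert np.all(lb.ilm <= lb.rpe)
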