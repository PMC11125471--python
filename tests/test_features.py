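"""Fovea detection and the nine-feature extraction."""

import numpy as np
import pytest

from octexan.blobs import Blob, extract_candidates
from octexan.features import (
    BoundaryUndefinedError,
    detect_fovea,
    distance_features,
    extract_features,
    shadow_features,
    shadow_geometry,
)
from octexan.pipeline import preprocess_image
from octexan.roi import LayerBoundaries, boundaries_from_mask
from octexan.synthetic import (
    EXAN,
    DISTRACTOR,
    IlmParams,
    SceneConfig,
    generate_scene,
)


def wing_curve(width=400, baseline=100.0, amp=10.0, fovea_x=200.0, depth=15.0,
               sign=1, sigma=14.0):
    x = np.arange(width, dtype=float)
    cx = (width - 1) / 2.0
    flank = amp * ((x - cx) / (width / 2.0)) ** 2
    dip = sign * depth * np.exp(-((x - fovea_x) ** 2) / (2 * sigma**2))
    return baseline - flank + dip


def make_blob(pixels):
    pix = np.asarray(pixels)
    y, x = pix[:, 0], pix[:, 1]
    return Blob(pixel_set=pix, bbox=(int(y.min()), int(x.min()), int(y.max()), int(x.max())),
                centroid=(float(y.mean()), float(x.mean())), area=len(pix))


class TestFovea:
    def test_recovers_dip_on_wing(self):
        f = detect_fovea(wing_curve(fovea_x=200.0, sign=1))
        assert abs(f.fovea_xy[0] - 200.0) <= 1.0
        assert not f.fallback
        p1, p2 = f.intersections
        assert p1 < f.fovea_xy[0] < p2

    def test_recovers_mountain_apex(self):
        f = detect_fovea(wing_curve(fovea_x=190.0, sign=-1))
        assert abs(f.fovea_xy[0] - 190.0) <= 1.0

    def test_straight_ilm_falls_back_flagged(self):
        f = detect_fovea(np.full(100, 80.0))
        assert f.fallback

    def test_translation_equivariance(self):
        curve = wing_curve(width=200, fovea_x=90.0)
        base = detect_fovea(curve)
        k = 17
        shifted = np.concatenate([np.full(k, np.nan), curve])
        moved = detect_fovea(shifted)
        assert moved.fovea_xy[0] == pytest.approx(base.fovea_xy[0] + k)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            detect_fovea(np.array([1.0, 2.0, np.nan]))

    def test_generator_ground_truth_both_signs(self):
        for sign in (1, -1):
            cfg = SceneConfig(ilm=IlmParams(fovea_x=120.0, fovea_sign=sign),
                              speckle_sigma=0.0, rng_seed=4)
            scene = generate_scene(cfg)
            lb = boundaries_from_mask(scene.roi_mask)
            f = detect_fovea(lb.ilm)
            assert abs(f.fovea_xy[0] - 120.0) <= 2.0


class TestDistances:
    def layers(self, width=300):
        ilm = np.full(width, 40.0)
        rpe = np.full(width, 140.0)
        mask = np.zeros((160, width), bool)
        mask[40:141, :] = True
        return LayerBoundaries(ilm=ilm, rpe=rpe, roi_mask=mask)

    def fovea_at(self, x):
        from octexan.features import FoveaResult

        return FoveaResult((float(x), 40.0), (0.0, 40.0), (0.0, 1.0))

    def test_fovea_distance_direct(self):
        blob = make_blob([(100, 120)])
        f5, _f6, _f7 = distance_features(blob, self.fovea_at(100), self.layers())
        assert f5 == 20.0

    def test_blob_on_ilm_zero_distance(self):
        blob = make_blob([(40, 50)])
        _f5, f6, _f7 = distance_features(blob, self.fovea_at(0), self.layers())
        assert f6 == 0.0

    def test_matches_scalar_oracle_on_random_blobs(self):
        rng = np.random.default_rng(17)
        width = 300
        ilm = 40 + 5 * np.sin(np.arange(width) / 30.0)
        rpe = 140 + 3 * np.cos(np.arange(width) / 50.0)
        layers = LayerBoundaries(ilm=ilm, rpe=rpe, roi_mask=np.ones((200, width), bool))
        fovea = self.fovea_at(150.3)
        for _ in range(100):
            cy, cx = rng.integers(50, 130), rng.integers(5, width - 5)
            pix = [(cy + dy, cx + dx) for dy in (0, 1) for dx in (0, 1) if rng.random() < 0.8]
            pix = pix or [(cy, cx)]
            blob = make_blob(pix)
            f5, f6, f7 = distance_features(blob, fovea, layers)
            # independent scalar computation
            xb = sum(p[1] for p in pix) / len(pix)
            yb = sum(p[0] for p in pix) / len(pix)
            x0 = int(np.floor(xb))
            t = xb - x0
            yi = (1 - t) * ilm[x0] + t * ilm[min(x0 + 1, width - 1)]
            yr = (1 - t) * rpe[x0] + t * rpe[min(x0 + 1, width - 1)]
            assert f5 == pytest.approx(abs(xb - 150.3), abs=1e-9)
            assert f6 == pytest.approx(abs(yb - yi), abs=1e-9)
            assert f7 == pytest.approx(abs(yb - yr), abs=1e-9)

    def test_undefined_boundary_errors_with_blob(self):
        width = 50
        ilm = np.full(width, np.nan)
        ilm[:10] = 20.0
        layers = LayerBoundaries(ilm=ilm, rpe=np.full(width, 40.0), roi_mask=np.ones((50, width), bool))
        blob = make_blob([(30, 30)])
        with pytest.raises(BoundaryUndefinedError):
            distance_features(blob, self.fovea_at(0), layers)


class TestShadow:
    def test_constant_regions_closed_form(self):
        img = np.full((60, 60), 0.2)
        blob = make_blob([(10 + dy, 20 + dx) for dy in range(2) for dx in range(4)])
        g = shadow_geometry(blob)
        assert (g.w, g.h, g.u, g.d) == (4, 6, 1, 5)
        top = 11 + g.u
        img[top : top + g.h, 20:24] = 0.1                       # middle
        img[top : top + g.h, 20 - (g.w + g.d) : 24 - (g.w + g.d)] = 0.4   # left
        img[top : top + g.h, 20 + (g.w + g.d) : 24 + (g.w + g.d)] = 0.35  # right
        f8, f9 = shadow_features(blob, img)
        assert f8 == pytest.approx(0.3, abs=1e-12)
        assert f9 == pytest.approx(0.25, abs=1e-12)

    def test_uniform_image_zero_contrast(self):
        blob = make_blob([(5, 5), (5, 6)])
        assert shadow_features(blob, np.full((30, 30), 0.7)) == (0.0, 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 40)) * 0.5
        blob = make_blob([(10, 10), (10, 11), (11, 10), (11, 11)])
        a = shadow_features(blob, img)
        b = shadow_features(blob, img + 0.3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_middle_rectangle_off_image(self):
        blob = make_blob([(28, 5), (29, 5)])
        assert shadow_features(blob, np.random.default_rng(0).random((30, 30))) == (0.0, 0.0)

    def test_shadowed_blob_scores_higher_than_distractor(self):
        cfg = SceneConfig(speckle_sigma=0.0, shadow_attenuation=0.3, n_cysts=0, rng_seed=11)
        scene = generate_scene(cfg)
        _norm, enh = preprocess_image(scene.image)
        scores = {EXAN: [], DISTRACTOR: []}
        for b in scene.blobs:
            f8, f9 = shadow_features(make_blob(b.pixels), enh.pixels)
            scores[b.label].append(f8 + f9)
        assert min(scores[EXAN]) > max(scores[DISTRACTOR])


class TestExtractFeatures:
    def test_single_pixel_blob(self):
        img = np.full((50, 50), 0.1)
        img[20, 10] = 0.8
        layers = LayerBoundaries(ilm=np.full(50, 5.0), rpe=np.full(50, 45.0),
                                 roi_mask=np.ones((50, 50), bool))
        from octexan.features import FoveaResult

        fovea = FoveaResult((25.0, 5.0), (0.0, 5.0), (0.0, 1.0))
        table = extract_features([make_blob([(20, 10)])], img, fovea, layers)
        row = table.iloc[0]
        assert row.f1 == row.f2 == row.f3 == 0.8
        assert row.f4 == 1

    def test_two_pixel_blob_intensity_stats(self):
        img = np.zeros((30, 30))
        img[10, 10], img[10, 11] = 0.7, 0.9
        layers = LayerBoundaries(ilm=np.full(30, 2.0), rpe=np.full(30, 28.0),
                                 roi_mask=np.ones((30, 30), bool))
        from octexan.features import FoveaResult

        fovea = FoveaResult((15.0, 2.0), (0.0, 2.0), (0.0, 1.0))
        row = extract_features([make_blob([(10, 10), (10, 11)])], img, fovea, layers).iloc[0]
        assert (row.f1, row.f2, row.f3, row.f4) == (pytest.approx(0.8), 0.7, 0.9, 2)

    def test_feature_invariants_on_full_scene(self):
        scene = generate_scene(SceneConfig(rng_seed=2))
        _norm, enh = preprocess_image(scene.image)
        lb = boundaries_from_mask(scene.roi_mask)
        cands = extract_candidates(enh, scene.roi_mask)
        assert cands
        fovea = detect_fovea(lb.ilm)
        table = extract_features(cands, enh, fovea, lb)
        assert len(table) == len(cands)
        assert (table.f2 <= table.f1 + 1e-12).all() and (table.f1 <= table.f3 + 1e-12).all()
        assert (table.f4 >= 1).all()
        assert (table[["f5", "f6", "f7", "f8", "f9"]] >= 0).all().all()
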