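"""White-balance, scale calibration, resizing and paired augmentation."""

import numpy as np
import pytest

from nsr_screen import preprocess as pp
from nsr_screen import synthetic as syn
from nsr_screen.io_consensus import BinaryMask, NsrImage
from nsr_screen.segmentation import dice


def _image(px):
    return NsrImage(pixels=np.asarray(px, dtype=np.uint8),
                    participant_id="p", time_min=5)


def _full_region(shape):
    return BinaryMask(pixels=np.ones(shape, dtype=bool), kind="white_ref")


class TestWhiteBalance:
    def test_pure_white_reference_is_identity(self):
        px = np.tile(np.array([255, 255, 255], dtype=np.uint8), (6, 6, 1))
        img = _image(px)
        out = pp.white_balance(img, _full_region((6, 6)))
        assert np.array_equal(out.pixels, px)

    def test_uniform_cast_maps_to_white(self):
        # gains 255/(100,200,50) = (2.55, 1.275, 5.1): every pixel -> white
        px = np.tile(np.array([100, 200, 50], dtype=np.uint8), (5, 7, 1))
        out = pp.white_balance(_image(px), _full_region((5, 7)))
        assert np.array_equal(out.pixels, np.full((5, 7, 3), 255, dtype=np.uint8))

    def test_gains_follow_perfect_reflector_arithmetic(self):
        px = np.zeros((4, 8, 3), dtype=np.uint8)
        px[:, :4] = (200, 100, 50)   # white-reference half
        px[:, 4:] = (100, 50, 25)    # skin half
        region = BinaryMask(pixels=np.arange(8)[None, :].repeat(4, 0) < 4,
                            kind="white_ref")
        out = pp.white_balance(_image(px), region)
        # skin scales by the same per-channel gains 255/(200,100,50)
        expected = np.array([100, 50, 25]) * 255.0 / np.array([200, 100, 50])
        assert np.abs(out.pixels[0, 6].astype(float) - expected).max() <= 1
        assert np.abs(out.pixels[0, 0].astype(float) - 255).max() == 0

    def test_idempotent_within_one_level(self):
        # near-homogeneous white patch, as the label provides in practice
        rng = np.random.default_rng(4)
        px = np.clip(rng.normal(150, 20, (10, 10, 3)), 0, 255).astype(np.uint8)
        patch = np.zeros((10, 10), dtype=bool)
        patch[3:7, 3:7] = True
        px[patch] = np.clip(rng.normal(235, 2, (patch.sum(), 3)), 0, 254)
        region = BinaryMask(pixels=patch, kind="white_ref")
        once = pp.white_balance(_image(px), region)
        twice = pp.white_balance(once, region)
        assert np.abs(twice.pixels.astype(int) - once.pixels.astype(int)).max() <= 1

    def test_removes_a_known_color_cast_from_a_render(self):
        p = syn.Participant(id="HC001", group="HC")
        row = {0.1: 0.2, 0.01: 0.1, 0.001: 0.05, 0.0001: 0.0}
        clean_cfg = syn.RenderConfig(cast_range=(1.0, 1.0), noise_sd=0.0,
                                     distance_range=(1.0, 1.0))
        cast_cfg = syn.RenderConfig(cast_range=(0.7, 1.3), noise_sd=0.0,
                                    distance_range=(1.0, 1.0))
        clean, _, lbl = syn.render_image(p, 10, row, clean_cfg,
                                         np.random.default_rng(1))
        cast, _, _ = syn.render_image(p, 10, row, cast_cfg,
                                      np.random.default_rng(1))
        # white-balance both so exposure is comparable, then compare skin
        fixed = pp.white_balance(cast, pp.find_white_reference(cast, lbl))
        base = pp.white_balance(clean, pp.find_white_reference(clean, lbl))
        diff = np.abs(fixed.pixels.astype(float).mean((0, 1))
                      - base.pixels.astype(float).mean((0, 1)))
        assert diff.max() < 6  # mean channel within a few intensity levels

    def test_empty_region_rejected(self, flat_image):
        with pytest.raises(ValueError, match="empty"):
            pp.white_balance(flat_image, BinaryMask(
                pixels=np.zeros((40, 80), dtype=bool), kind="white_ref"))


class TestScaleCalibration:
    def _label(self, shape, r0, r1, c0, c1):
        px = np.zeros(shape, dtype=bool)
        px[r0:r1, c0:c1] = True
        return BinaryMask(pixels=px, kind="label")

    def test_label_at_target_is_identity(self, flat_image):
        spec = pp.CalibrationSpec(target_label_px=30)
        label = self._label((40, 80), 5, 15, 10, 40)  # major axis 30
        out = pp.calibrate_scale(flat_image, label, spec)
        assert out.shape_hw == flat_image.shape_hw

    def test_half_size_label_doubles_the_image(self, flat_image):
        spec = pp.CalibrationSpec(target_label_px=60)
        label = self._label((40, 80), 5, 15, 10, 40)  # measured 30 -> factor 2
        out = pp.calibrate_scale(flat_image, label, spec)
        assert out.shape_hw == (80, 160)

    def test_degenerate_label_rejected(self, flat_image):
        label = self._label((40, 80), 0, 2, 0, 2)
        with pytest.raises(ValueError, match="degenerate"):
            pp.calibrate_scale(flat_image, label, pp.CalibrationSpec())

    def test_camera_distance_invariance_of_flush_areas(self):
        # same scene at two distances: calibrated flush areas agree within 5%
        p = syn.Participant(id="HC001", group="HC")
        row = {0.1: 0.2, 0.01: 0.12, 0.001: 0.0, 0.0001: 0.0}
        areas = []
        for d in (0.85, 1.2):
            cfg = syn.RenderConfig(distance_range=(d, d), noise_sd=0.0)
            img, flm, lbm = syn.render_image(p, 15, row, cfg,
                                             np.random.default_rng(2))
            _, _, fl = pp.preprocess_pair(img, lbm, flm)
            areas.append(fl.area_px)
        assert abs(areas[0] - areas[1]) / max(areas) < 0.05


class TestResize:
    def test_identity_at_target_shape(self):
        spec = pp.CalibrationSpec()
        px = np.random.default_rng(0).integers(0, 255, (128, 512, 3)).astype(np.uint8)
        img = _image(px)
        out = pp.resize_to_input(img, spec=spec)
        assert out.pixels is px or np.array_equal(out.pixels, px)

    def test_all_true_mask_stays_all_true(self):
        mask = BinaryMask(pixels=np.ones((40, 90), dtype=bool))
        img = _image(np.zeros((40, 90, 3), dtype=np.uint8))
        _, m = pp.resize_to_input(img, mask)
        assert m.pixels.shape == (128, 512)
        assert m.pixels.all()

    def test_mask_area_scales_with_pixel_area_ratio(self):
        px = np.zeros((32, 128), dtype=bool)
        px[10:16, 40:52] = True  # 72 px block
        img = _image(np.zeros((32, 128, 3), dtype=np.uint8))
        _, m = pp.resize_to_input(img, BinaryMask(pixels=px))
        ratio = (128 * 512) / (32 * 128)
        assert m.pixels.sum() == pytest.approx(72 * ratio, rel=0.1)
        assert m.pixels.dtype == bool


class TestAugmentation:
    def _pair(self, seed=0, shape=(32, 64)):
        rng = np.random.default_rng(seed)
        img = _image(rng.integers(0, 255, (*shape, 3)).astype(np.uint8))
        mask = BinaryMask(pixels=rng.random(shape) < 0.2)
        return img, mask

    def test_zero_magnitudes_are_exact_identity(self):
        img, mask = self._pair()
        out_i, out_m = pp.augment_pair(img, mask, pp.AugmentParams.identity(), 99)
        assert np.array_equal(out_i.pixels, img.pixels)
        assert np.array_equal(out_m.pixels, mask.pixels)

    def test_certain_hflip_is_an_involution(self):
        img, mask = self._pair()
        params = pp.AugmentParams.identity()
        params.p_hflip = 1.0
        once = pp.augment_pair(img, mask, params, 7)
        twice = pp.augment_pair(once[0], once[1], params, 7)
        assert np.array_equal(twice[0].pixels, img.pixels)
        assert np.array_equal(twice[1].pixels, mask.pixels)

    def test_flip_keeps_image_mask_alignment(self):
        img, mask = self._pair(3)
        params = pp.AugmentParams.identity()
        params.p_hflip = 1.0
        params.p_vflip = 1.0
        _, out_m = pp.augment_pair(img, mask, params, 11)
        expected = BinaryMask(pixels=mask.pixels[::-1, ::-1].copy())
        assert dice(out_m, expected) == 1.0

    def test_fixed_draw_seed_is_bit_reproducible(self):
        img, mask = self._pair(5)
        params = pp.AugmentParams()
        a = pp.augment_pair(img, mask, params, 123)
        b = pp.augment_pair(img, mask, params, 123)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_photometric_jitter_never_touches_the_mask(self):
        img, mask = self._pair(6)
        params = pp.AugmentParams.identity()
        params.brightness_delta = 0.3
        params.contrast_delta = 0.3
        params.saturation_delta = 0.3
        for seed in range(5):
            _, out_m = pp.augment_pair(img, mask, params, seed)
            assert np.array_equal(out_m.pixels, mask.pixels)

    def test_geometric_transform_applied_identically(self):
        # a rotated pair still overlays: mask follows the image content
        img, mask = self._pair(8, shape=(48, 48))
        # paint the mask region white so it is trackable in the image
        px = img.pixels.copy()
        px[mask.pixels] = 255
        img = _image(px)
        params = pp.AugmentParams.identity()
        params.max_rotation_deg = 30
        out_i, out_m = pp.augment_pair(img, mask, params, 21)
        bright = out_i.pixels.mean(axis=2) > 160
        overlap = (bright & out_m.pixels).sum()
        assert overlap / max(out_m.pixels.sum(), 1) > 0.85
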