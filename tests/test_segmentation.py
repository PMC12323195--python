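"""Patient-level splits, overlap metrics, and segmenter training behaviour.

Training tests run on deliberately tiny frames (32 x 64) so the suite stays
fast; the full-resolution behaviour is exercised by the acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsr_screen import preprocess as pp
from nsr_screen import segmentation as seg
from nsr_screen.io_consensus import BinaryMask, NsrImage


def _mask(arr):
    return BinaryMask(pixels=np.asarray(arr, dtype=bool))


class TestSplit:
    def test_reference_cohort_splits_90_10_20(self):
        ids = [f"p{i}" for i in range(120)]
        s = seg.split_by_participant(ids, seed=1)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (90, 10, 20)
        assert s.train_ids | s.val_ids | s.test_ids == set(ids)

    def test_small_cohort_scales_proportionally(self):
        s = seg.split_by_participant([f"p{i}" for i in range(12)], seed=0)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (9, 1, 2)

    def test_deterministic_per_seed_and_varying_across_seeds(self):
        ids = [f"p{i}" for i in range(60)]
        a = seg.split_by_participant(ids, seed=5)
        b = seg.split_by_participant(ids, seed=5)
        c = seg.split_by_participant(ids, seed=6)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.train_ids != c.train_ids

    def test_no_participant_leaks_across_splits(self):
        ids = [f"p{i}" for i in range(37)]
        s = seg.split_by_participant(ids, seed=2)
        assert not (s.train_ids & s.val_ids)
        assert not (s.train_ids & s.test_ids)
        assert not (s.val_ids & s.test_ids)
        assert len(s.train_ids) + len(s.val_ids) + len(s.test_ids) == 37

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            seg.split_by_participant(["a", "b"], seed=0)


class TestOverlapMetrics:
    def test_identical_and_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        a[2:5, 2:5] = True
        b = np.zeros((10, 10), dtype=bool)
        b[6:9, 6:9] = True
        assert seg.dice(_mask(a), _mask(a)) == 1.0
        assert seg.iou(_mask(a), _mask(a)) == 1.0
        assert seg.dice(_mask(a), _mask(b)) == 0.0
        assert seg.iou(_mask(a), _mask(b)) == 0.0

    def test_counting_oracle_100_100_overlap_60(self):
        p = np.zeros(400, dtype=bool)
        g = np.zeros(400, dtype=bool)
        p[:100] = True
        g[40:140] = True  # overlap 60
        p, g = _mask(p.reshape(20, 20)), _mask(g.reshape(20, 20))
        assert seg.dice(p, g) == pytest.approx(0.60)
        assert seg.iou(p, g) == pytest.approx(60 / 140)

    def test_empty_conventions(self):
        e = _mask(np.zeros((4, 4)))
        f = _mask(np.ones((4, 4)))
        assert seg.dice(e, e) == 1.0 and seg.iou(e, e) == 1.0
        assert seg.dice(e, f) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.dice(_mask(np.zeros((4, 4))), _mask(np.zeros((4, 5))))

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2 ** 30))
    def test_dice_iou_identity_symmetry_and_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = _mask(rng.random((12, 18)) < 0.4)
        g = _mask(rng.random((12, 18)) < 0.4)
        d, i = seg.dice(p, g), seg.iou(p, g)
        assert d == pytest.approx(2 * i / (1 + i))
        assert i <= d <= 1
        assert seg.dice(g, p) == d and seg.iou(g, p) == i
        pf = _mask(p.pixels[::-1, ::-1])
        gf = _mask(g.pixels[::-1, ::-1])
        assert seg.dice(pf, gf) == pytest.approx(d)


def _tiny_scene(seed, shape=(32, 64)):
    """A crude mini arm frame: dark background with a bright blob to find."""
    rng = np.random.default_rng(seed)
    px = np.full((*shape, 3), 120, dtype=np.float64)
    px += rng.normal(0, 4, px.shape)
    mask = np.zeros(shape, dtype=bool)
    r, c = rng.integers(8, shape[0] - 8), rng.integers(10, shape[1] - 10)
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    mask[(rr - r) ** 2 + (cc - c) ** 2 < 36] = True
    px[mask] = (200, 80, 80)
    img = NsrImage(pixels=np.clip(px, 0, 255).astype(np.uint8),
                   participant_id=f"s{seed}", time_min=5)
    return img, BinaryMask(pixels=mask)


TINY = dict(encoder_depth=2, base_channels=6, input_hw=(32, 64), lr=2e-3, seed=0)


class TestSegmenterModel:
    def test_output_shape_and_range_on_zero_image(self):
        model = seg.build_segmenter(seg.SegModelConfig(**TINY))
        img = NsrImage(pixels=np.zeros((32, 64, 3), dtype=np.uint8),
                       participant_id="z", time_min=1)
        proba = model.predict_proba([img])
        assert proba.shape == (1, 32, 64)
        assert np.isfinite(proba).all()
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_indivisible_spatial_dims_rejected(self):
        with pytest.raises(ValueError):
            seg.SegModelConfig(encoder_depth=4, input_hw=(36, 64))

    def test_threshold_rule_is_geq(self):
        model = seg.build_segmenter(seg.SegModelConfig(**TINY))

        class Stub:
            def forward(self, x, want_cache=False):
                return np.full((*x.shape[:3], 1), 0.5, dtype=np.float32)

        model.net = Stub()
        img = NsrImage(pixels=np.zeros((32, 64, 3), dtype=np.uint8),
                       participant_id="z", time_min=1)
        assert seg.predict_mask(model, img, threshold=0.5).pixels.all()
        assert not seg.predict_mask(model, img, threshold=0.50001).pixels.any()

    def test_constant_probability_maps(self):
        model = seg.build_segmenter(seg.SegModelConfig(**TINY))

        class Stub:
            def __init__(self, v):
                self.v = v

            def forward(self, x, want_cache=False):
                return np.full((*x.shape[:3], 1), self.v, dtype=np.float32)

        img = NsrImage(pixels=np.zeros((32, 64, 3), dtype=np.uint8),
                       participant_id="z", time_min=1)
        model.net = Stub(0.7)
        assert seg.predict_mask(model, img).pixels.all()
        model.net = Stub(0.3)
        assert not seg.predict_mask(model, img).pixels.any()

    def test_checkpoint_round_trip(self, tmp_path):
        model = seg.build_segmenter(seg.SegModelConfig(**TINY))
        img, _ = _tiny_scene(1)
        before = model.predict_proba([img])
        model.save(tmp_path / "ckpt.pkl")
        loaded = seg.Segmenter.load(tmp_path / "ckpt.pkl")
        assert np.array_equal(loaded.predict_proba([img]), before)
        assert loaded.config == model.config


class TestTraining:
    def test_overfits_a_single_tiny_scene(self):
        img, mask = _tiny_scene(7)
        cfg = seg.SegModelConfig(epochs=70, batch_size=8, **TINY)
        model = seg.build_segmenter(cfg)
        hist = seg.train_segmenter(model, [img] * 8, [mask] * 8, [img], [mask])
        assert all(np.isfinite(hist["loss"]))
        assert hist["best_val_dice"] >= 0.95
        assert hist["best_val_dice"] >= hist["val_dice"][0]

    def test_augmentation_does_not_hurt_shifted_test_distribution(self):
        train = [_tiny_scene(s) for s in range(10)]
        # shifted distribution: the same scenes mirrored
        test = [(NsrImage(pixels=i.pixels[:, ::-1].copy(), participant_id=i.participant_id,
                          time_min=i.time_min), BinaryMask(pixels=m.pixels[:, ::-1].copy()))
                for i, m in [_tiny_scene(s) for s in range(20, 26)]]
        aug = pp.AugmentParams(max_rotation_deg=10, max_shift_frac=0.05,
                               scale_range=(0.95, 1.05), p_hflip=0.5, p_vflip=0.0,
                               brightness_delta=0.1, contrast_delta=0.1,
                               saturation_delta=0.1)
        dices = {}
        for name, params in [("plain", None), ("aug", aug)]:
            cfg = seg.SegModelConfig(epochs=25, batch_size=10, **TINY)
            model = seg.build_segmenter(cfg)
            seg.train_segmenter(model, [t[0] for t in train], [t[1] for t in train],
                                augment=params)
            m = seg.evaluate(model, [t[0] for t in test], [t[1] for t in test])
            dices[name] = m.dice
        assert dices["aug"] >= dices["plain"] - 0.02

    def test_empty_training_set_rejected(self):
        model = seg.build_segmenter(seg.SegModelConfig(**TINY))
        with pytest.raises(ValueError):
            seg.train_segmenter(model, [], [])
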