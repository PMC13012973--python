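"""Mask refinement, segment cropping, and segmenter training contracts."""

import numpy as np
import pytest
from skimage.morphology import closing, disk

from digibone import nn
from digibone.errors import DataError, EmptySegmentError, InvalidInputError
from digibone.segmentation import (MaskSet, RefineConfig, SegTrainConfig,
                                   crop_segments, load_segmenter, predict_masks,
                                   refine_masks, resize_image, save_segmenter,
                                   train_segmenter)
from digibone.synthdata import SEGMENTS, PhantomParams, SamplerConfig, \
    generate_phantom, sample_phantoms


def empty_like(shape):
    return np.zeros(shape, dtype=bool)


def maskset_single(seg, mask):
    d = {s: empty_like(mask.shape) for s in SEGMENTS}
    d[seg] = mask
    return MaskSet.from_dict(d)


class TestRefineMasks:
    def test_area_rule_removes_speck(self):
        img = np.full((64, 64), 0.8)
        m = empty_like((64, 64))
        m[10:35, 10:30] = True          # 500 px blob
        m[50:51, 50:53] = True          # 3 px speck
        cfg = RefineConfig(min_area=50, mean_intensity_min=0.0,
                           morph_open_radius=0, morph_close_radius=0)
        out = refine_masks(maskset_single("carpals", m), img, cfg)
        assert out.carpals[10:35, 10:30].all()
        assert not out.carpals[50:, 50:].any()

    def test_intensity_rule_removes_dark_component(self):
        img = np.full((64, 64), 0.05)   # dark background under the blob
        m = empty_like((64, 64))
        m[10:30, 10:30] = True
        cfg = RefineConfig(min_area=10, mean_intensity_min=0.2,
                           morph_open_radius=0, morph_close_radius=0)
        out = refine_masks(maskset_single("wrist", m), img, cfg)
        assert not out.wrist.any()      # empty mask returned, caller decides

    def test_clean_masks_are_fixed_point(self):
        img = np.full((64, 64), 0.8)
        a = empty_like((64, 64)); a[5:20, 5:20] = True
        b = empty_like((64, 64)); b[30:45, 5:20] = True
        c = empty_like((64, 64)); c[50:60, 30:60] = True
        cfg = RefineConfig(min_area=1, mean_intensity_min=0.0,
                           morph_open_radius=0, morph_close_radius=0,
                           keep_top_k=5)
        raw = MaskSet(shortbones=a, carpals=b, wrist=c)
        out = refine_masks(raw, img, cfg)
        for seg in SEGMENTS:
            assert np.array_equal(out.as_dict()[seg], raw.as_dict()[seg])

    def test_idempotent_on_phantom_masks(self, male_scale):
        s = generate_phantom(PhantomParams(image_size=128, fullhand_age=120,
                                           seed=6), male_scale)
        cfg = RefineConfig(min_area=3, morph_open_radius=0,
                           morph_close_radius=1, keep_top_k=12)
        raw = MaskSet.from_dict(s.masks)
        once = refine_masks(raw, s.image, cfg)
        twice = refine_masks(once, s.image, cfg)
        for seg in SEGMENTS:
            assert np.array_equal(once.as_dict()[seg], twice.as_dict()[seg])

    def test_never_adds_pixels_beyond_closing(self, male_scale):
        s = generate_phantom(PhantomParams(image_size=128, fullhand_age=60,
                                           seed=7), male_scale)
        cfg = RefineConfig(min_area=3, morph_open_radius=0,
                           morph_close_radius=2, keep_top_k=12)
        out = refine_masks(MaskSet.from_dict(s.masks), s.image, cfg)
        for seg in SEGMENTS:
            envelope = closing(s.masks[seg], disk(2))
            assert not (out.as_dict()[seg] & ~envelope).any()

    def test_refined_masks_pairwise_disjoint(self):
        img = np.full((32, 32), 0.8)
        a = empty_like((32, 32)); a[5:20, 5:20] = True
        b = empty_like((32, 32)); b[10:25, 10:28] = True   # overlaps a, larger
        cfg = RefineConfig(min_area=1, mean_intensity_min=0.0,
                           morph_open_radius=0, morph_close_radius=0)
        out = refine_masks(MaskSet(shortbones=a, carpals=b,
                                   wrist=empty_like((32, 32))), img, cfg)
        assert not (out.shortbones & out.carpals).any()
        # contested pixels went to the larger component
        assert out.carpals[12, 12] and not out.shortbones[12, 12]


class TestCropSegments:
    def test_corner_blob_bounding_box(self):
        img = np.random.default_rng(0).uniform(0.5, 1.0, (256, 256))
        m = empty_like((256, 256))
        m[0:10, 0:10] = True
        masks = MaskSet.from_dict({s: (m if s == "carpals" else np.ones_like(m))
                                   for s in SEGMENTS})
        crops = crop_segments(img, masks, out_size=32, pad_fraction=0.0)
        # the blob crop equals the masked 10x10 corner, upscaled to 32x32
        from skimage.transform import resize
        want = resize((img * m)[0:10, 0:10], (32, 32), order=1,
                      anti_aliasing=True, preserve_range=True)
        np.testing.assert_allclose(crops["carpals"], want, atol=1e-12)

    def test_outside_mask_is_zero(self, male_scale):
        s = generate_phantom(PhantomParams(image_size=128, fullhand_age=120,
                                           seed=8), male_scale)
        crops = crop_segments(s.image, MaskSet.from_dict(s.masks), out_size=64)
        # background in the phantom is ~0.1 everywhere, so exact zeros in the
        # crop can only come from masking / letterbox padding
        for seg in SEGMENTS:
            assert (crops[seg] == 0.0).mean() > 0.1
            assert crops[seg].shape == (64, 64)

    def test_full_mask_identity_box(self):
        img = np.random.default_rng(1).uniform(0, 1, (64, 64))
        full = np.ones((64, 64), dtype=bool)
        crops = crop_segments(img, MaskSet(shortbones=full, carpals=full,
                                           wrist=full),
                              out_size=64, pad_fraction=0.0)
        np.testing.assert_allclose(crops["wrist"], img, atol=1e-12)

    def test_empty_mask_names_segment(self):
        img = np.zeros((32, 32))
        full = np.ones((32, 32), dtype=bool)
        with pytest.raises(EmptySegmentError, match="carpals"):
            crop_segments(img, MaskSet(shortbones=full,
                                       carpals=empty_like((32, 32)),
                                       wrist=full))


class TestTrainPredict:
    def test_empty_manifest_rejected(self):
        with pytest.raises(DataError):
            train_segmenter([])

    def test_missing_masks_rejected(self, male_scale):
        s = generate_phantom(PhantomParams(seed=1), male_scale)
        s.masks = None
        with pytest.raises(DataError):
            train_segmenter([s])

    def test_training_deterministic(self, male_scale):
        samples = sample_phantoms(6, SamplerConfig(image_size=96), male_scale, 3)
        cfg = SegTrainConfig(epochs=2, seed=5)
        m1 = train_segmenter(samples, cfg)
        m2 = train_segmenter(samples, cfg)
        assert m1.loss_trajectory == m2.loss_trajectory

    def test_predict_shape_contract_and_no_update(self, male_scale, tmp_path):
        samples = sample_phantoms(6, SamplerConfig(image_size=96), male_scale, 3)
        model = train_segmenter(samples, SegTrainConfig(epochs=2, seed=5))
        with pytest.raises(InvalidInputError):
            predict_masks(model, samples[0].image)   # 96 != 64
        img = resize_image(samples[0].image, model.input_size)
        before = {k: v.copy() for k, v in nn.state_dict(model.net).items()}
        predict_masks(model, img, tta=True)
        predict_masks(model, img, tta=False)
        after = nn.state_dict(model.net)
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_checkpoint_round_trip(self, male_scale, tmp_path):
        samples = sample_phantoms(6, SamplerConfig(image_size=96), male_scale, 3)
        model = train_segmenter(samples, SegTrainConfig(epochs=2, seed=5))
        save_segmenter(model, tmp_path / "seg")
        back = load_segmenter(tmp_path / "seg")
        img = resize_image(samples[0].image, model.input_size)
        for tta in (False, True):
            a = predict_masks(model, img, tta=tta)
            b = predict_masks(back, img, tta=tta)
            for seg in SEGMENTS:
                assert np.array_equal(a.as_dict()[seg], b.as_dict()[seg])
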