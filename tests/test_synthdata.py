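"""Phantom generator: determinism, maturity monotonicity, shift transform,
prediction tables, and dataset round-trips."""

import itertools

import numpy as np
import pytest

from digibone.errors import ConfigError, InvalidInputError
from digibone.synthdata import (SEGMENTS, PhantomParams, SamplerConfig,
                                ShiftParams, apply_domain_shift,
                                generate_phantom, generate_prediction_table,
                                load_dataset, make_dataset, phantom_metrics,
                                sample_phantoms)


class TestPhantom:
    def test_deterministic(self, male_scale):
        p = PhantomParams(image_size=128, fullhand_age=120, seed=7)
        a = generate_phantom(p, male_scale)
        b = generate_phantom(p, male_scale)
        assert np.array_equal(a.image, b.image)
        for seg in SEGMENTS:
            assert np.array_equal(a.masks[seg], b.masks[seg])

    def test_synchrony(self, male_scale):
        s = generate_phantom(PhantomParams(fullhand_age=100, seed=1), male_scale)
        assert set(s.segment_ages.values()) == {s.y}

    def test_masks_disjoint_and_nontrivial(self, male_scale):
        for age in (24, 120, 216):
            s = generate_phantom(PhantomParams(fullhand_age=age, seed=2), male_scale)
            for a, b in itertools.combinations(SEGMENTS, 2):
                assert not (s.masks[a] & s.masks[b]).any()
            for seg in SEGMENTS:
                assert s.masks[seg].sum() >= 20

    def test_carpal_area_strictly_grows_with_offset(self, male_scale):
        base = PhantomParams(image_size=128, fullhand_age=96, seed=3)
        plus = PhantomParams(image_size=128, fullhand_age=96,
                             segment_offsets=(0, 24, 0), seed=3)
        a0 = phantom_metrics(generate_phantom(base, male_scale))["carpal_area"]
        a1 = phantom_metrics(generate_phantom(plus, male_scale))["carpal_area"]
        assert a1 > a0

    def test_maturity_cues_monotone_in_age(self, male_scale):
        ages = np.arange(12, 229, 12)
        m = [phantom_metrics(generate_phantom(
            PhantomParams(image_size=128, fullhand_age=float(a), seed=3),
            male_scale)) for a in ages]
        areas = [x["carpal_area"] for x in m]
        sgaps = [x["shortbone_gap_rows"] for x in m]
        wgaps = [x["wrist_gap_rows"] for x in m]
        assert all(b >= a for a, b in zip(areas, areas[1:]))
        assert all(b <= a for a, b in zip(sgaps, sgaps[1:]))
        assert all(b <= a for a, b in zip(wgaps, wgaps[1:]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ConfigError):
            PhantomParams(image_size=32)

    def test_sex_scale_mismatch_rejected(self, female_scale):
        from digibone.errors import DataError
        with pytest.raises(DataError):
            generate_phantom(PhantomParams(sex="male"), female_scale)


class TestDomainShift:
    def test_identity(self):
        img = np.random.default_rng(0).uniform(0, 1, (16, 16))
        out = apply_domain_shift(img, ShiftParams(gain=1, offset=0, gamma=1))
        np.testing.assert_allclose(out, img)

    def test_affine_arithmetic(self):
        img = np.full((4, 4), 0.2)
        out = apply_domain_shift(img, ShiftParams(gain=0.5, offset=0.4, gamma=1))
        np.testing.assert_allclose(out, 0.5)

    def test_gamma_arithmetic(self):
        img = np.array([[0.2, 0.9]])
        out = apply_domain_shift(img, ShiftParams(gamma=2))
        np.testing.assert_allclose(out, [[0.04, 0.81]])

    def test_invertible_on_nonclipped_range(self):
        img = np.linspace(0.1, 0.9, 64).reshape(8, 8)
        p = ShiftParams(gain=0.8, offset=0.05, gamma=1.3)
        out = apply_domain_shift(img, p)
        back = ((out - p.offset) / p.gain) ** (1 / p.gamma)
        np.testing.assert_allclose(back, img, atol=1e-12)

    @pytest.mark.parametrize("kw", [{"gain": 0}, {"gain": -1}, {"gamma": 0}])
    def test_invalid_params(self, kw):
        with pytest.raises(InvalidInputError):
            ShiftParams(**kw)


class TestPredictionTable:
    def test_noiseless_collapses_to_latent(self, male_scale):
        recs = generate_prediction_table(50, 0.4, 0, 0, male_scale, seed=2)
        for r in recs:
            assert abs(r.fh - r.seg_avg) < 1e-9
            assert r.y == pytest.approx(
                min(male_scale.classes, key=lambda g: (abs(r.fh - g), g)))

    def test_deterministic(self, male_scale):
        a = generate_prediction_table(2000, 0.3, 6, 6, male_scale, seed=5)
        b = generate_prediction_table(2000, 0.3, 6, 6, male_scale, seed=5)
        assert all(x.fh == y.fh and x.seg_avg == y.seg_avg and x.y == y.y
                   for x, y in zip(a, b))

    def test_seg_avg_is_exact_mean(self, male_scale):
        recs = generate_prediction_table(100, 0.7, 4, 8, male_scale, seed=1)
        for r in recs:
            mean = (r.seg_shortbones + r.seg_carpals + r.seg_wrist) / 3
            assert r.seg_avg == pytest.approx(mean, abs=1e-9)

    @pytest.mark.parametrize("kw", [
        {"n": 0}, {"alpha0": 1.5}, {"noise_sd_fh": -1}, {"noise_sd_seg": -1}])
    def test_invalid_inputs(self, male_scale, kw):
        base = dict(n=10, alpha0=0.5, noise_sd_fh=1, noise_sd_seg=1,
                    scale=male_scale, seed=0)
        base.update(kw)
        with pytest.raises(InvalidInputError):
            generate_prediction_table(**base)


class TestMakeDataset:
    def test_counts_labels_and_determinism(self, tmp_path, male_scale):
        sampler = SamplerConfig(image_size=96)
        manifest = make_dataset(10, sampler, male_scale, tmp_path / "d1", seed=4)
        assert len(manifest) == 10
        assert len(list((tmp_path / "d1").glob("*.png"))) == 40  # 10 images + 30 masks
        for col in ("fullhand_age", "shortbones_age", "carpals_age", "wrist_age"):
            assert set(manifest[col]).issubset(set(male_scale.classes))
        make_dataset(10, sampler, male_scale, tmp_path / "d2", seed=4)
        assert (tmp_path / "d1" / "manifest.csv").read_bytes() == \
               (tmp_path / "d2" / "manifest.csv").read_bytes()

    def test_load_round_trip(self, tmp_path, male_scale):
        sampler = SamplerConfig(image_size=96)
        make_dataset(3, sampler, male_scale, tmp_path, seed=4)
        samples = load_dataset(tmp_path / "manifest.csv")
        originals = sample_phantoms(3, sampler, male_scale, 4)
        for got, want in zip(samples, originals):
            assert got.y == want.y and got.segment_ages == want.segment_ages
            # images pass through 8-bit PNG quantization
            assert np.abs(got.image - want.image).max() <= 1 / 255 + 1e-9
            for seg in SEGMENTS:
                assert np.array_equal(got.masks[seg], want.masks[seg])
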