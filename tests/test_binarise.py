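import numpy as np
import pytest

from cvai import (
    BinarisationConfig,
    DegenerateMaskError,
    EmptyFieldError,
    ParameterError,
    adaptive_binarise,
    apply_clahe,
    compute_cvai,
    run_pipeline,
    subtract_retinal_vessels,
)
from cvai.binarise import DARK_ON_LIGHT, LIGHT_ON_DARK, gaussian_kernel
from cvai.image_io import BinaryMask, ChannelImage, FundusImage
from cvai.synth import SyntheticSpec, generate_eye


def brute_force_adaptive(px, block, offset, polarity):
    """Independent per-pixel Gaussian-weighted local-mean thresholding.

    Same stated conventions as the module (symmetric border reflection,
    strict inequality, sigma tied to block size) but computed pixel by
    pixel from first principles.
    """
    kernel = gaussian_kernel(block)
    r = block // 2
    pad = np.pad(px.astype(np.float64), r, mode="symmetric")
    out = np.zeros(px.shape, dtype=bool)
    for i in range(px.shape[0]):
        for j in range(px.shape[1]):
            mean = float((pad[i : i + block, j : j + block] * kernel).sum())
            v = float(px[i, j])
            out[i, j] = v < mean - offset if polarity == DARK_ON_LIGHT else v > mean + offset
    return out


def brute_force_clahe_lut(tile, clip_limit):
    """Per-tile clipped-histogram equalisation mapping, from the definition."""
    area = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(float)
    clip = max(1.0, clip_limit * area / 256.0)
    excess = np.clip(hist - clip, 0.0, None).sum()
    hist = np.minimum(hist, clip) + excess / 256.0
    cdf = np.cumsum(hist)
    return np.clip(np.rint(cdf * 255.0 / area), 0, 255)


class TestClahe:
    def test_constant_image_stays_constant(self, bin_cfg):
        out = apply_clahe(ChannelImage(np.full((64, 64), 120, dtype=np.uint8)), bin_cfg)
        assert np.ptp(out.pixels) == 0

    def test_tile_larger_than_image_rejected(self):
        cfg = BinarisationConfig(clahe_tile=100)
        with pytest.raises(ParameterError, match="tile"):
            apply_clahe(ChannelImage(np.zeros((64, 64), dtype=np.uint8)), cfg)

    def test_pure_regions_match_per_tile_oracle(self, rng):
        """Outside the outermost tile centres the mapping is a single tile's
        clipped equalisation; check both tiles of a two-tile image."""
        cfg = BinarisationConfig(clahe_tile=8, clahe_clip_limit=2.0)
        left = rng.integers(20, 80, (8, 8))
        right = rng.integers(150, 230, (8, 8))
        img = np.concatenate([left, right], axis=1).astype(np.uint8)
        out = apply_clahe(ChannelImage(img), cfg).pixels
        lut0 = brute_force_clahe_lut(img[:, :8], 2.0)
        lut1 = brute_force_clahe_lut(img[:, 8:], 2.0)
        np.testing.assert_array_equal(out[:, :4], lut0[img[:, :4]])
        np.testing.assert_array_equal(out[:, 12:], lut1[img[:, 12:]])

    def test_contrast_not_reduced_on_vessel_image(self, sample_eye, bin_cfg):
        g = ChannelImage(sample_eye.image.pixels[..., 1])
        out = apply_clahe(g, bin_cfg)
        assert np.ptp(out.pixels) >= np.ptp(g.pixels)


class TestAdaptiveBinarise:
    def test_constant_image_all_background(self, bin_cfg):
        ch = ChannelImage(np.full((32, 32), 77, dtype=np.uint8))
        for pol in (DARK_ON_LIGHT, LIGHT_ON_DARK):
            assert not adaptive_binarise(ch, bin_cfg, pol, block=11).pixels.any()

    def test_single_dark_pixel_detected_exactly(self):
        cfg = BinarisationConfig(adaptive_offset_C=5.0)
        px = np.full((32, 32), 255, dtype=np.uint8)
        px[16, 16] = 0
        mask = adaptive_binarise(ChannelImage(px), cfg, DARK_ON_LIGHT, block=11).pixels
        expected = np.zeros((32, 32), dtype=bool)
        expected[16, 16] = True
        np.testing.assert_array_equal(mask, expected)

    def test_even_block_rejected(self, bin_cfg):
        with pytest.raises(ParameterError, match="odd"):
            adaptive_binarise(
                ChannelImage(np.zeros((32, 32), dtype=np.uint8)), bin_cfg,
                DARK_ON_LIGHT, block=10,
            )

    def test_block_exceeding_image_rejected(self, bin_cfg):
        with pytest.raises(ParameterError):
            adaptive_binarise(
                ChannelImage(np.zeros((16, 16), dtype=np.uint8)), bin_cfg,
                DARK_ON_LIGHT, block=17,
            )

    @pytest.mark.parametrize("block,offset", [(3, 0.0), (7, 4.0), (11, 8.0)])
    def test_matches_bruteforce_oracle(self, rng, block, offset):
        cfg = BinarisationConfig(adaptive_offset_C=offset)
        px = rng.integers(0, 256, (24, 24), dtype=np.uint8)
        for pol in (DARK_ON_LIGHT, LIGHT_ON_DARK):
            got = adaptive_binarise(ChannelImage(px), cfg, pol, block=block).pixels
            np.testing.assert_array_equal(got, brute_force_adaptive(px, block, offset, pol))

    def test_foreground_monotone_in_offset(self, rng):
        px = rng.integers(0, 256, (48, 48), dtype=np.uint8)
        counts = []
        for c in (0.0, 2.0, 4.0, 8.0, 16.0):
            cfg = BinarisationConfig(adaptive_offset_C=c)
            counts.append(
                adaptive_binarise(ChannelImage(px), cfg, LIGHT_ON_DARK, block=9).count
            )
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSubtractRetinalVessels:
    def test_empty_mask_is_identity(self, rng):
        r = ChannelImage(rng.integers(0, 256, (64, 64), dtype=np.uint8))
        empty = BinaryMask(np.zeros((64, 64), dtype=bool), "retinal_vessel")
        out = subtract_retinal_vessels(r, empty)
        np.testing.assert_array_equal(out.pixels, r.pixels)

    def test_dark_vessel_infilled_to_background(self):
        px = np.full((64, 64), 200, dtype=np.uint8)
        mask = np.zeros((64, 64), dtype=bool)
        mask[:, 30:33] = True  # 3-px-wide vertical vessel
        px[mask] = 40
        out = subtract_retinal_vessels(
            ChannelImage(px), BinaryMask(mask, "retinal_vessel")
        )
        assert np.abs(out.pixels[mask].astype(int) - 200).max() <= 2
        np.testing.assert_array_equal(out.pixels[~mask], px[~mask])

    def test_mask_covering_most_of_field_rejected(self):
        px = np.full((64, 64), 200, dtype=np.uint8)
        mask = np.ones((64, 64), dtype=bool)
        mask[:3] = False
        with pytest.raises(DegenerateMaskError, match="90%"):
            subtract_retinal_vessels(ChannelImage(px), BinaryMask(mask, "retinal_vessel"))


class TestOpticDisc:
    def test_detected_on_synthetic_eye(self, sample_eye, sample_result):
        det = sample_result.masks["optic_disc"].pixels
        truth = sample_eye.truth_disc.pixels
        ty, tx = np.nonzero(truth)
        dy, dx = np.nonzero(det)
        centroid_err = np.hypot(ty.mean() - dy.mean(), tx.mean() - dx.mean())
        dice = 2 * (det & truth).sum() / (det.sum() + truth.sum())
        assert centroid_err <= 5.0
        assert dice >= 0.6

    def test_no_saturated_region_gives_empty_mask(self, bin_cfg, rng):
        from cvai.binarise import detect_optic_disc

        chans = [
            ChannelImage(rng.integers(80, 140, (96, 96), dtype=np.uint8))
            for _ in range(3)
        ]
        assert not detect_optic_disc(*chans, bin_cfg).pixels.any()

    def test_disc_missing_in_one_channel_gives_empty_product(self, bin_cfg, rng):
        from cvai.binarise import detect_optic_disc

        base = rng.integers(80, 120, (96, 96), dtype=np.uint8)
        r = base.copy()
        g = base.copy()
        r[40:60, 40:60] = 250
        g[40:60, 40:60] = 250
        b = np.full((96, 96), 100, dtype=np.uint8)  # no bright structure in B
        assert not detect_optic_disc(
            ChannelImage(r), ChannelImage(g), ChannelImage(b), bin_cfg
        ).pixels.any()


class TestComputeCvai:
    def test_empty_final_mask_gives_zero(self):
        fov = BinaryMask(np.ones((64, 64), dtype=bool), "field_of_view")
        final = BinaryMask(np.zeros((64, 64), dtype=bool), "choroidal_vessel")
        assert compute_cvai(final, fov).cvai == 0.0

    def test_definition_is_exact(self):
        fov = np.zeros((64, 64), dtype=bool)
        fov[:25, :40] = True  # 1000-px field
        final = np.zeros((64, 64), dtype=bool)
        final[:5, :10] = True  # 50 px inside the field
        res = compute_cvai(
            BinaryMask(final, "choroidal_vessel"), BinaryMask(fov, "field_of_view")
        )
        assert (res.cvr_px, res.ir_px, res.cvai) == (50, 1000, 0.05)

    def test_empty_field_raises(self):
        empty = BinaryMask(np.zeros((64, 64), dtype=bool), "field_of_view")
        final = BinaryMask(np.zeros((64, 64), dtype=bool), "choroidal_vessel")
        with pytest.raises(EmptyFieldError):
            compute_cvai(final, empty)


class TestPipeline:
    def test_blank_eye_has_zero_cvai(self, bin_cfg):
        blank = SyntheticSpec(n_choroidal_vessels=0, n_retinal_vessels=0, disc_radius_px=0)
        eye = generate_eye(blank, 300.0, seed=0)
        assert run_pipeline(eye.image, bin_cfg).cvai == 0.0

    def test_deterministic(self, sample_eye, bin_cfg, sample_result):
        again = run_pipeline(sample_eye.image, bin_cfg)
        assert again.cvai == sample_result.cvai
        assert again.cvr_px == sample_result.cvr_px
        np.testing.assert_array_equal(
            again.masks["final"].pixels, sample_result.masks["final"].pixels
        )

    def test_result_invariants(self, sample_result):
        res = sample_result
        assert res.cvai == res.cvr_px / res.ir_px
        assert 0.0 <= res.cvai <= 1.0
        final = res.masks["final"].pixels
        assert not (final & res.masks["optic_disc"].pixels).any()
        assert not (final & ~res.masks["field_of_view"].pixels).any()

    def test_rotation_equivariance(self, sample_eye, bin_cfg, sample_result):
        rotated = FundusImage(np.rot90(sample_eye.image.pixels).copy(), eye_id="rot")
        res_rot = run_pipeline(rotated, bin_cfg)
        assert abs(res_rot.cvai - sample_result.cvai) <= 0.01 * sample_result.cvai
        m0 = np.rot90(sample_result.masks["final"].pixels)
        m1 = res_rot.masks["final"].pixels
        iou = (m0 & m1).sum() / max((m0 | m1).sum(), 1)
        assert iou > 0.9

    def test_cvai_non_increasing_under_attenuation(self, spec, bin_cfg):
        """Fixed geometry and seed: thicker choroid (stronger attenuation)
        never increases the detected vessel area."""
        values = [
            run_pipeline(generate_eye(spec, t, seed=7).image, bin_cfg).cvai
            for t in (50.0, 150.0, 250.0, 350.0, 450.0, 600.0)
        ]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[0] > values[-1]  # the effect is real, not flat


class TestConfig:
    def test_even_block_rejected_in_config(self):
        with pytest.raises(ParameterError):
            BinarisationConfig(adaptive_block=24)

    def test_unknown_option_rejected(self):
        with pytest.raises(ParameterError, match="unknown"):
            BinarisationConfig.from_mapping({"block_size": 25})

    def test_block_scaling_stays_odd(self, bin_cfg):
        for diameter in (100, 256, 512, 700):
            b = bin_cfg.scaled_block(diameter)
            assert b % 2 == 1 and b >= 3
        assert bin_cfg.scaled_block(512) == bin_cfg.adaptive_block
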