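"""Preprocessing: continuous remap, CLAHE, paired resize and augmentation."""

import numpy as np
import pytest

from pixelbnn.preprocess import (
    AugmentConfig,
    FormatError,
    FundusImage,
    ParameterError,
    VesselMask,
    apply_orientation,
    augment_pair,
    clahe_enhance,
    draw_geometry,
    invert_orientation,
    remap_to_continuous,
    resize_pair,
)


def make_image(h=64, w=64, seed=0):
    rng = np.random.default_rng(seed)
    return FundusImage(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8))


class TestRemap:
    @pytest.mark.parametrize(
        "value,expected", [(0, -0.5), (255, 0.5), (51, -0.3), (128, 128 / 255 - 0.5)]
    )
    def test_endpoint_and_interior_values(self, value, expected):
        img = FundusImage(np.full((4, 4, 3), value, dtype=np.uint8))
        out = remap_to_continuous(img).pixels
        assert np.allclose(out, expected, atol=1e-6)

    def test_affine_and_order_preserving(self):
        ramp = np.arange(256, dtype=np.uint8)
        img = FundusImage(np.stack([ramp] * 3, axis=-1)[None].repeat(2, axis=0))
        out = remap_to_continuous(img).pixels
        diffs = np.diff(out[0, :, 0])
        assert np.all(diffs > 0)
        assert np.allclose(diffs, 1.0 / 255.0, atol=1e-6)

    def test_rejects_non_three_channel(self):
        with pytest.raises(FormatError):
            FundusImage(np.zeros((4, 4, 2), dtype=np.uint8))

    def test_rgba_alpha_dropped(self):
        rgba = np.zeros((4, 4, 4), dtype=np.uint8)
        rgba[..., 3] = 255
        assert FundusImage.from_array(rgba).pixels.shape == (4, 4, 3)


class TestClahe:
    def test_constant_image_stays_spatially_constant(self):
        img = FundusImage(np.full((64, 64, 3), 120, dtype=np.uint8))
        out = clahe_enhance(img).pixels
        for c in range(3):
            assert np.ptp(out[:, :, c]) <= 1  # flat field has no contrast to enhance

    def test_preserves_drive_sized_dimensions(self):
        img = make_image(584, 565)
        out = clahe_enhance(img)
        assert out.pixels.shape == (584, 565, 3)
        assert out.pixels.dtype == np.uint8

    def test_checkerboard_tile_spread_widens(self):
        # two close gray levels; equalization should push them apart in
        # every tile of the 8x8 grid
        h = w = 64
        checker = np.indices((h, w)).sum(axis=0) % 8 < 4
        base = np.where(checker, 118, 138).astype(np.uint8)
        img = FundusImage(np.stack([base] * 3, axis=-1))
        out = clahe_enhance(img, clip_limit=4.0).pixels
        gray_in = base.astype(float)
        gray_out = out.mean(axis=2)
        for i in range(0, h, 8):
            for j in range(0, w, 8):
                tile_in = gray_in[i : i + 8, j : j + 8]
                tile_out = gray_out[i : i + 8, j : j + 8]
                assert tile_out.std() > tile_in.std()

    def test_tile_grid_too_fine_raises(self):
        with pytest.raises(ParameterError):
            clahe_enhance(make_image(6, 6), tile_grid=(8, 8))

    def test_nonpositive_clip_limit_raises(self):
        with pytest.raises(ParameterError):
            clahe_enhance(make_image(), clip_limit=0.0)


class TestResizePair:
    def test_drive_size_to_256(self):
        img = make_image(584, 565)
        mask = VesselMask((np.random.default_rng(0).random((584, 565)) > 0.9).astype(np.uint8))
        out_img, out_mask = resize_pair(img, mask, 256)
        assert out_img.pixels.shape == (256, 256, 3)
        assert out_mask.pixels.shape == (256, 256)
        assert set(np.unique(out_mask.pixels)) <= {0, 1}

    def test_identity_when_already_target_size(self):
        img = make_image(64, 64)
        mask = VesselMask(np.zeros((64, 64), dtype=np.uint8))
        out_img, out_mask = resize_pair(img, mask, 64)
        assert np.array_equal(out_img.pixels, img.pixels)
        assert np.array_equal(out_mask.pixels, mask.pixels)

    def test_all_ones_mask_stays_all_ones(self):
        img = make_image(100, 80)
        mask = VesselMask(np.ones((100, 80), dtype=np.uint8))
        _, out_mask = resize_pair(img, mask, 48)
        assert np.array_equal(out_mask.pixels, np.ones((48, 48), dtype=np.uint8))


def rotated_coordinate(r, c, h, w, k):
    """Where pixel (r, c) of an (h, w) raster lands after np.rot90(arr, k)."""
    for _ in range(k % 4):
        r, c = w - 1 - c, r
        h, w = w, h
    return r, c


class TestAugment:
    CFG = AugmentConfig(crop_min=48, crop_max=64, target_size=64)

    def test_fixed_seed_is_deterministic(self):
        img, mask = make_image(80, 80), VesselMask(
            (np.random.default_rng(1).random((80, 80)) > 0.9).astype(np.uint8)
        )
        a = augment_pair(img, mask, self.CFG, np.random.default_rng(7))
        b = augment_pair(img, mask, self.CFG, np.random.default_rng(7))
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)

    def test_crop_sides_within_configured_band(self):
        cfg = AugmentConfig()  # 216..256
        rng = np.random.default_rng(0)
        for _ in range(200):
            ch, cw, top, left, *_ = draw_geometry(cfg, rng, 584, 565)
            assert 216 <= ch <= 256 and 216 <= cw <= 256
            assert 0 <= top <= 584 - ch and 0 <= left <= 565 - cw

    def test_crop_exceeding_bounds_raises(self):
        with pytest.raises(ParameterError):
            draw_geometry(AugmentConfig(crop_min=100, crop_max=100), np.random.default_rng(0), 80, 80)

    def test_single_pixel_tracks_geometric_map(self):
        # crop window equal to target size, so no interpolation: the one set
        # pixel must land exactly where the coordinate map sends it
        cfg = AugmentConfig(crop_min=64, crop_max=64, target_size=64)
        img = make_image(96, 96)
        for seed in range(12):
            geom_rng = np.random.default_rng(seed)
            ch, cw, top, left, fh, fv, k = draw_geometry(cfg, geom_rng, 96, 96)
            r, c = top + 10, left + 20  # inside every crop window
            mask = np.zeros((96, 96), dtype=np.uint8)
            mask[r, c] = 1
            _, out_mask = augment_pair(
                img, VesselMask(mask), cfg, np.random.default_rng(seed)
            )
            rr, cc = r - top, c - left
            if fh:
                cc = cw - 1 - cc
            if fv:
                rr = ch - 1 - rr
            rr, cc = rotated_coordinate(rr, cc, ch, cw, k)
            expected = np.zeros_like(out_mask.pixels)
            expected[rr, cc] = 1
            assert np.array_equal(out_mask.pixels, expected)

    def test_indicator_commutes_on_random_sparse_masks(self):
        cfg = AugmentConfig(crop_min=64, crop_max=64, target_size=64)
        rng_mask = np.random.default_rng(3)
        img = make_image(96, 96)
        for seed in range(6):
            sparse = (rng_mask.random((96, 96)) > 0.98).astype(np.uint8)
            ch, cw, top, left, fh, fv, k = draw_geometry(
                cfg, np.random.default_rng(seed), 96, 96
            )
            _, out_mask = augment_pair(
                img, VesselMask(sparse), cfg, np.random.default_rng(seed)
            )
            manual = apply_orientation(
                sparse[top : top + ch, left : left + cw], fh, fv, k
            )
            assert np.array_equal(out_mask.pixels, manual)

    def test_orientation_roundtrip_is_lossless(self):
        arr = np.random.default_rng(0).integers(0, 256, size=(32, 32), dtype=np.uint8)
        for fh in (False, True):
            for fv in (False, True):
                for k in (0, 1, 2):
                    fwd = apply_orientation(arr, fh, fv, k)
                    assert np.array_equal(invert_orientation(fwd, fh, fv, k), arr)

    def test_photometric_jitter_never_touches_mask(self):
        img = make_image(80, 80)
        mask = VesselMask((np.random.default_rng(5).random((80, 80)) > 0.9).astype(np.uint8))
        tame = AugmentConfig(crop_min=64, crop_max=64, target_size=64,
                             brightness_delta_max=0.0, contrast_factor_range=(1.0, 1.0))
        wild = AugmentConfig(crop_min=64, crop_max=64, target_size=64,
                             brightness_delta_max=0.4, contrast_factor_range=(0.2, 2.0))
        out_tame = augment_pair(img, mask, tame, np.random.default_rng(11))
        out_wild = augment_pair(img, mask, wild, np.random.default_rng(11))
        assert np.array_equal(out_tame[1].pixels, out_wild[1].pixels)
        assert not np.array_equal(out_tame[0].pixels, out_wild[0].pixels)

    def test_output_range_is_continuous_space(self):
        img, mask = make_image(80, 80), VesselMask(np.zeros((80, 80), dtype=np.uint8))
        cont, _ = augment_pair(img, mask, self.CFG, np.random.default_rng(2))
        assert cont.pixels.min() >= -0.5 and cont.pixels.max() <= 0.5
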