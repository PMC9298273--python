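"""Unit tests for the z-stack -> normalized-crop pipeline."""

import numpy as np
import pytest

from phenoscreen.preprocessing import (BIII, DAPI, IMAGENET, PLACEHOLDER,
                                       ChannelCombination, RGBImage8, augment,
                                       autocontrast, compose_rgb,
                                       max_intensity_projection,
                                       preprocess_field, resize_and_normalize,
                                       tile, to_8bit)


class TestMaxIntensityProjection:
    def test_single_plane_is_identity(self, rng):
        plane = rng.integers(0, 65536, (1, 20, 20)).astype(np.uint16)
        assert np.array_equal(max_intensity_projection(plane), plane[0])

    def test_elementwise_max(self):
        stack = np.array([[[1, 5], [3, 2]], [[4, 0], [2, 9]]], dtype=np.uint16)
        assert np.array_equal(max_intensity_projection(stack),
                              np.array([[4, 5], [3, 9]]))

    def test_matches_bruteforce_loop(self, rng):
        stack = rng.integers(0, 65536, (5, 64, 64)).astype(np.uint16)
        expected = np.zeros((64, 64), dtype=np.uint16)
        for i in range(64):
            for j in range(64):
                m = 0
                for k in range(5):
                    m = max(m, stack[k, i, j])
                expected[i, j] = m
        assert np.array_equal(max_intensity_projection(stack), expected)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_intensity_projection(np.zeros((0, 4, 4), dtype=np.uint16))


class TestComposeRGB:
    def test_8bit_conversion_rule(self):
        ch = np.array([[65535, 255], [256, 0]], dtype=np.uint16)
        out = to_8bit(ch)
        assert out.tolist() == [[255, 0], [1, 0]]

    def test_single_channel_fills_only_its_slot(self, rng):
        dapi = rng.integers(0, 65536, (8, 8)).astype(np.uint16)
        img = compose_rgb({DAPI: dapi}, ChannelCombination((DAPI,)))
        assert np.array_equal(img.pixels[:, :, 2], to_8bit(dapi))  # blue
        assert not img.pixels[:, :, 0].any() and not img.pixels[:, :, 1].any()
        assert img.slot_map == (PLACEHOLDER, PLACEHOLDER, DAPI)

    def test_full_combination_slot_assignment(self, rng):
        chans = {m: rng.integers(0, 65536, (8, 8)).astype(np.uint16)
                 for m in (DAPI, BIII, "FUS")}
        img = compose_rgb(chans, ChannelCombination((DAPI, BIII, "FUS")))
        assert np.array_equal(img.pixels[:, :, 0], to_8bit(chans[BIII]))
        assert np.array_equal(img.pixels[:, :, 1], to_8bit(chans["FUS"]))
        assert np.array_equal(img.pixels[:, :, 2], to_8bit(chans[DAPI]))

    def test_missing_marker_named_in_error(self):
        with pytest.raises(KeyError, match="FUS"):
            compose_rgb({DAPI: np.zeros((4, 4), dtype=np.uint16)},
                        ChannelCombination((DAPI, "FUS")))


class TestAutocontrast:
    def test_constant_channel_unchanged(self):
        px = np.full((10, 10, 3), 77, dtype=np.uint8)
        img = RGBImage8(px, (BIII, "FUS", DAPI))
        assert np.array_equal(autocontrast(img).pixels, px)

    def test_zero_cutoff_full_stretch(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:, :, 2] = np.linspace(10, 110, 100).reshape(10, 10).astype(np.uint8)
        img = RGBImage8(px, (PLACEHOLDER, PLACEHOLDER, DAPI))
        out = autocontrast(img, cutoff_percent=0.0).pixels[:, :, 2]
        assert out.min() == 0 and out.max() == 255

    def test_tail_trim_anchors_on_trimmed_range(self, rng):
        # 1000 pixels: one outlier at 255, the rest in [50, 100]; a 0.1%
        # cutoff removes exactly one pixel from each tail.
        vals = rng.integers(50, 101, 1000).astype(np.uint8)
        vals[0] = 255
        px = np.zeros((20, 50, 3), dtype=np.uint8)
        px[:, :, 0] = vals.reshape(20, 50)
        out = autocontrast(RGBImage8(px, (BIII, PLACEHOLDER, PLACEHOLDER)),
                           cutoff_percent=0.1).pixels[:, :, 0]
        # oracle 1: remap anchored on the trimmed range
        body = np.sort(vals)[1:-1]
        lo, hi = int(body[0]), int(body[-1])
        remapped = (vals.astype(float) - lo) * 255.0 / (hi - lo)
        assert np.all(np.abs(out - np.clip(remapped, 0, 255).reshape(20, 50)) <= 1)
        assert out.reshape(-1)[0] == 255  # outlier clipped to white
        # oracle 2: Pillow's reference implementation, bit-for-bit
        from PIL import Image, ImageOps
        pillow = np.array(ImageOps.autocontrast(
            Image.fromarray(vals.reshape(20, 50), mode="L"), cutoff=0.1))
        assert np.array_equal(out, pillow)

    @pytest.mark.parametrize("cutoff,seed", [(0.0, 1), (0.1, 2), (1.0, 3), (5.0, 4)])
    def test_agrees_with_pillow_reference(self, cutoff, seed):
        from PIL import Image, ImageOps
        r = np.random.default_rng(seed)
        ch = r.integers(0, 256, (60, 60)).astype(np.uint8)
        px = np.zeros((60, 60, 3), dtype=np.uint8)
        px[:, :, 1] = ch
        out = autocontrast(RGBImage8(px, (PLACEHOLDER, "FUS", PLACEHOLDER)),
                           cutoff_percent=cutoff).pixels[:, :, 1]
        pillow = np.array(ImageOps.autocontrast(Image.fromarray(ch, mode="L"),
                                                cutoff=cutoff))
        assert np.array_equal(out, pillow)

    def test_placeholder_slots_stay_zero(self, rng):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[:, :, 2] = rng.integers(0, 256, (10, 10))
        out = autocontrast(RGBImage8(px, (PLACEHOLDER, PLACEHOLDER, DAPI)))
        assert not out.pixels[:, :, 0].any() and not out.pixels[:, :, 1].any()


class TestTile:
    def test_1080_gives_16_tiles_of_270(self, rng):
        px = rng.integers(0, 256, (1080, 1080, 3)).astype(np.uint8)
        tiles = tile(RGBImage8(px, (BIII, PLACEHOLDER, DAPI)))
        assert len(tiles) == 16
        assert all(t.pixels.shape == (270, 270, 3) for t in tiles)

    def test_reassembly_is_pixel_exact(self, rng):
        px = rng.integers(0, 256, (540, 540, 3)).astype(np.uint8)
        tiles = tile(RGBImage8(px, (BIII, PLACEHOLDER, DAPI)), tile_size=270)
        assert len(tiles) == 4
        top = np.concatenate([tiles[0].pixels, tiles[1].pixels], axis=1)
        bot = np.concatenate([tiles[2].pixels, tiles[3].pixels], axis=1)
        assert np.array_equal(np.concatenate([top, bot], axis=0), px)

    def test_indivisible_rejected(self):
        px = np.zeros((500, 500, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            tile(RGBImage8(px), tile_size=270)


class TestResizeNormalize:
    def test_constant_red_channel_value(self):
        px = np.zeros((270, 270, 3), dtype=np.uint8)
        px[:, :, 0] = 255
        out = resize_and_normalize(RGBImage8(px, (BIII, PLACEHOLDER, PLACEHOLDER)))
        assert out.shape == (224, 224, 3)
        assert np.allclose(out[:, :, 0], (1.0 - 0.485) / 0.229)

    def test_placeholder_slot_constant(self, rng):
        px = np.zeros((270, 270, 3), dtype=np.uint8)
        px[:, :, 0] = rng.integers(0, 256, (270, 270))
        out = resize_and_normalize(RGBImage8(px, (BIII, PLACEHOLDER, PLACEHOLDER)))
        assert np.allclose(out[:, :, 1], (0.0 - 0.456) / 0.224)
        assert np.allclose(out[:, :, 2], (0.0 - 0.406) / 0.225)


class TestAugment:
    def test_six_outputs_in_fixed_order(self, rng):
        img = rng.normal(size=(16, 16, 3))
        outs = augment(img)
        assert len(outs) == 6
        assert np.array_equal(outs[0], img)
        assert np.array_equal(outs[1], np.rot90(img, axes=(0, 1)))
        assert np.array_equal(outs[2], img[:, ::-1])
        assert np.array_equal(outs[3], img[::-1, :])
        assert np.array_equal(outs[4], np.rot90(img[:, ::-1], axes=(0, 1)))
        assert np.array_equal(outs[5], np.rot90(img[::-1, :], axes=(0, 1)))

    def test_constant_image_six_identical(self):
        img = np.full((8, 8, 3), 3.0)
        outs = augment(img)
        assert all(np.array_equal(o, img) for o in outs)

    def test_mirror_is_involution(self, rng):
        img = rng.normal(size=(8, 8, 3))
        assert np.array_equal(augment(augment(img)[2])[2], img)

    def test_nonsquare_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(rng.normal(size=(8, 10, 3)))


def test_preprocess_field_equals_chained_steps(rng):
    """The composed operation must match MIP -> 8-bit -> compose ->
    autocontrast -> tile -> resize -> normalize applied step by step."""
    chans = {m: rng.integers(0, 40000, (3, 540, 540)).astype(np.uint16)
             for m in (DAPI, BIII)}
    combo = ChannelCombination((DAPI, BIII))
    got = preprocess_field(chans, combo, tile_size=270, size=64)

    mips = {m: max_intensity_projection(z) for m, z in chans.items()}
    rgb = autocontrast(compose_rgb(mips, combo), 0.1)
    expected = [resize_and_normalize(t, IMAGENET, 64) for t in tile(rgb, 270)]
    assert len(got) == len(expected) == 4
    for g, e in zip(got, expected):
        assert np.array_equal(g, e)
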