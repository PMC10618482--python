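"""Resizing, normalization, augmentation and mask downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sporeseg as ss
from sporeseg.preprocess import (
    DEFAULT_AUGMENTATIONS,
    downsample_mask,
)


def _pair(h, w, seed=0):
    rng = np.random.default_rng(seed)
    return ss.AnnotatedImage(
        pixels=rng.random((h, w)).astype(np.float32),
        mask=rng.integers(0, 9, (h, w)).astype(np.uint8),
    )


class TestResize:
    def test_working_scale_geometry(self):
        """3000x2500 raw micrographs resample to the 2048x1664 working size."""
        img = _pair(3000 // 4, 2500 // 4)  # same aspect, desk memory
        cfg = ss.PreprocessConfig(target_size=(2048 // 4, 1664 // 4))
        out = ss.resize_pair(img, cfg)
        assert out.spatial_shape == (512, 416)
        assert out.mask.shape == (512, 416)

    def test_constant_image_stays_constant(self):
        img = ss.AnnotatedImage(pixels=np.full((64, 48), 0.7, dtype=np.float32))
        out = ss.resize_pair(img, ss.PreprocessConfig(target_size=(32, 32)))
        assert np.allclose(out.pixels, 0.7)

    def test_nearest_neighbour_cannot_invent_labels(self):
        rng = np.random.default_rng(1)
        mask = rng.choice([3, 4, 8], size=(100, 80)).astype(np.uint8)
        img = ss.AnnotatedImage(pixels=rng.random((100, 80)), mask=mask)
        out = ss.resize_pair(img, ss.PreprocessConfig(target_size=(64, 48)))
        assert set(np.unique(out.mask)) <= {3, 4, 8}

    def test_target_dims_must_divide_16(self):
        with pytest.raises(ValueError):
            ss.PreprocessConfig(target_size=(100, 64))


class TestNormalize:
    def test_maps_range_to_unit_interval(self):
        img = ss.AnnotatedImage(pixels=np.linspace(10, 250, 48).reshape(6, 8))
        out = ss.normalize(img)
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0

    def test_constant_maps_to_zeros(self):
        out = ss.normalize(ss.AnnotatedImage(pixels=np.full((4, 4), 9.0)))
        assert np.all(out.pixels == 0.0)

    def test_idempotent(self):
        img = ss.AnnotatedImage(pixels=np.random.default_rng(0).random((16, 16)))
        once = ss.normalize(img)
        twice = ss.normalize(once)
        assert np.allclose(once.pixels, twice.pixels, atol=1e-6)

    def test_rejects_nonfinite(self):
        px = np.ones((4, 4))
        px[0, 0] = np.nan
        with pytest.raises(ValueError):
            ss.normalize(ss.AnnotatedImage(pixels=px))


class TestAugmentation:
    def test_six_outputs_preserving_size(self, small_phantom):
        outs = ss.augment_pair(small_phantom)
        assert len(outs) == 6
        for out in outs:
            assert out.spatial_shape == small_phantom.spatial_shape
            assert out.mask.shape == small_phantom.mask.shape

    def test_sixty_four_inputs_make_384_outputs(self):
        pool = ss.generate_dataset(64, ss.PhantomConfig(image_size=(64, 64)), seed=5)
        augmented = [out for img in pool for out in ss.augment_pair(img)]
        assert len(augmented) == 384

    def test_hflip_is_involution(self, small_phantom):
        once = DEFAULT_AUGMENTATIONS.apply(small_phantom, "hflip")
        back = DEFAULT_AUGMENTATIONS.apply(once, "hflip")
        assert np.array_equal(back.pixels, small_phantom.pixels)
        assert np.array_equal(back.mask, small_phantom.mask)

    def test_mask_moves_with_pixels(self, small_phantom):
        """The same geometric map is applied to image and mask."""
        out = DEFAULT_AUGMENTATIONS.apply(small_phantom, "vflip")
        assert np.array_equal(out.mask, small_phantom.mask[::-1])
        assert np.array_equal(out.pixels, small_phantom.pixels[::-1])

    def test_requires_mask(self):
        img = ss.AnnotatedImage(pixels=np.zeros((32, 32)))
        with pytest.raises(ValueError):
            ss.augment_pair(img)

    @pytest.mark.parametrize("name", ["rot180", "hflip", "vflip"])
    def test_size_preserving_transforms_commute_with_majority(self, small_phantom, name):
        """Factor-aligned transforms commute with 16x16 blockwise majority."""
        mask = small_phantom.mask
        t_then_down = downsample_mask(
            DEFAULT_AUGMENTATIONS.apply(small_phantom, name).mask
        )
        down = downsample_mask(mask)
        if name == "rot180":
            down_then_t = np.rot90(down, 2)
        elif name == "hflip":
            down_then_t = down[:, ::-1]
        else:
            down_then_t = down[::-1]
        assert np.array_equal(t_then_down, down_then_t)

    def test_rot90_commutes_on_family_sizes(self):
        """Pad-to-square offsets are 16-aligned for the working aspect family."""
        img = _pair(160, 128, seed=3)
        rot = DEFAULT_AUGMENTATIONS.apply(img, "rot90")
        t_then_down = downsample_mask(rot.mask)
        # same pad-rotate-crop, performed on the downsampled grid
        down = downsample_mask(img.mask)
        s = max(down.shape)
        py, px = s - down.shape[0], s - down.shape[1]
        sq = np.pad(down, ((py // 2, py - py // 2), (px // 2, px - px // 2)))
        rot_grid = np.rot90(sq, 1)
        oy = (rot_grid.shape[0] - down.shape[0]) // 2
        ox = (rot_grid.shape[1] - down.shape[1]) // 2
        down_then_t = rot_grid[oy : oy + down.shape[0], ox : ox + down.shape[1]]
        assert np.array_equal(t_then_down, down_then_t)


class TestDownsampleMask:
    def test_unanimous_block(self):
        assert downsample_mask(np.full((16, 16), 3, dtype=np.uint8))[0, 0] == 3

    def test_majority_wins(self):
        block = np.full((16, 16), 5, dtype=np.uint8)
        block.ravel()[:200] = 2  # 200 of 256 pixels are class 2
        assert downsample_mask(block)[0, 0] == 2

    def test_exact_tie_breaks_to_lowest_index(self):
        block = np.empty((16, 16), dtype=np.uint8)
        block.ravel()[:128] = 6
        block.ravel()[128:] = 4
        assert downsample_mask(block)[0, 0] == 4

    def test_zero_excluded_from_vote(self):
        block = np.zeros((16, 16), dtype=np.uint8)
        block.ravel()[:10] = 7  # 10 labeled pixels beat 246 unannotated
        assert downsample_mask(block)[0, 0] == 7

    def test_all_zero_block_stays_zero(self):
        assert downsample_mask(np.zeros((16, 16), dtype=np.uint8))[0, 0] == 0

    def test_grid_shape(self):
        out = downsample_mask(np.ones((160, 128), dtype=np.uint8))
        assert out.shape == (10, 8)

    def test_rejects_nondivisible_dims(self):
        with pytest.raises(ValueError):
            downsample_mask(np.zeros((17, 16), dtype=np.uint8))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_output_labels_subset_of_input(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.integers(0, 9, (48, 32)).astype(np.uint8)
        out = downsample_mask(mask)
        assert set(np.unique(out)) <= set(np.unique(mask)) | {0}
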