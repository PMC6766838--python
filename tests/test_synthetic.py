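import numpy as np
import pytest

from ricelodging import SceneSpec, augment, build_dataset, generate_scene, random_crop
from ricelodging.synthetic import (apply_affine, draw_affine, split_sizes)
from skimage.transform import AffineTransform


class TestSceneGeneration:
    def test_zero_fraction_gives_empty_mask(self):
        spec = SceneSpec(height=96, width=128, target_lodged_fraction=0.0,
                         n_blobs=0, seed=1)
        img, mask = generate_scene(spec, "rgb")
        assert mask.pixels.sum() == 0
        assert img.pixels.shape == (96, 128, 3)

    def test_realized_fraction_tracks_target(self):
        spec = SceneSpec(height=192, width=256, target_lodged_fraction=0.55,
                         n_blobs=4, seed=7)
        _, mask = generate_scene(spec, "rgb")
        assert 0.44 <= mask.area_fraction() <= 0.66

    def test_same_seed_bit_identical(self):
        spec = SceneSpec(height=96, width=96, seed=3)
        a_img, a_mask = generate_scene(spec, "rgn")
        b_img, b_mask = generate_scene(spec, "rgn")
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert np.array_equal(a_mask.pixels, b_mask.pixels)

    def test_distinct_seeds_distinct_scenes(self):
        a, _ = generate_scene(SceneSpec(height=96, width=96, seed=3), "rgb")
        b, _ = generate_scene(SceneSpec(height=96, width=96, seed=4), "rgb")
        assert not np.array_equal(a.pixels, b.pixels)

    def test_no_blobs_with_positive_fraction_rejected(self):
        with pytest.raises(ValueError, match="n_blobs"):
            SceneSpec(n_blobs=0, target_lodged_fraction=0.3)

    def test_lodged_pixels_statistically_separable(self, small_scene):
        img, mask = small_scene
        lodged = mask.pixels.astype(bool)
        r = img.band("R")
        # default red shift is +60; the means must differ by at least half
        assert r[lodged].mean() - r[~lodged].mean() >= 30.0

    def test_rgn_variant_depresses_nir_in_lodged_areas(self):
        spec = SceneSpec(height=192, width=256, target_lodged_fraction=0.3,
                         n_blobs=3, seed=9)
        img, mask = generate_scene(spec, "rgn")
        nir = img.band("NIR")
        lodged = mask.pixels.astype(bool)
        assert nir[lodged].mean() < nir[~lodged].mean() - 30.0


class TestRandomCrop:
    def test_identity_crop_when_sizes_match(self, small_scene, rng):
        from ricelodging import BandImage, BinaryMask
        img, mask = small_scene
        sq_img = BandImage(img.pixels[:192, :192], img.channel_names)
        sq_mask = BinaryMask(mask.pixels[:192, :192])
        ci, cm = random_crop(sq_img, sq_mask, size=192, rng=rng)
        assert np.array_equal(ci.pixels, sq_img.pixels)
        assert np.array_equal(cm.pixels, sq_mask.pixels)

    def test_crop_matches_source_window(self, small_scene):
        img, mask = small_scene
        rng = np.random.default_rng(0)
        ci, cm = random_crop(img, mask, size=64, rng=rng)
        # locate the crop by matching the first row strip
        found = False
        for r0 in range(img.height - 63):
            for c0 in range(img.width - 63):
                if np.array_equal(img.pixels[r0:r0+64, c0:c0+64], ci.pixels):
                    assert np.array_equal(mask.pixels[r0:r0+64, c0:c0+64],
                                          cm.pixels)
                    found = True
                    break
            if found:
                break
        assert found

    def test_too_small_image_rejected(self, small_scene, rng):
        img, mask = small_scene
        with pytest.raises(ValueError, match="smaller"):
            random_crop(img, mask, size=512, rng=rng)


class TestAugmentation:
    def test_identity_transform_is_bit_identical(self, small_scene):
        img, mask = small_scene
        ident = AffineTransform()
        out_img, out_mask = apply_affine(img, mask, ident)
        assert np.array_equal(out_img.pixels, img.pixels)
        assert np.array_equal(out_mask.pixels, mask.pixels)

    def test_horizontal_flip_reverses_columns(self, small_scene):
        img, mask = small_scene
        h, w = mask.shape
        # flip about the vertical center axis
        flip = AffineTransform(matrix=np.array(
            [[-1, 0, w - 1.0], [0, 1, 0], [0, 0, 1]]))
        _, out_mask = apply_affine(img, mask, flip)
        assert np.array_equal(out_mask.pixels, mask.pixels[:, ::-1])

    def test_flip_twice_is_identity(self, small_scene):
        img, mask = small_scene
        h, w = mask.shape
        flip = AffineTransform(matrix=np.array(
            [[-1, 0, w - 1.0], [0, 1, 0], [0, 0, 1]]))
        once_i, once_m = apply_affine(img, mask, flip)
        twice_i, twice_m = apply_affine(once_i, once_m, flip)
        assert np.array_equal(twice_m.pixels, mask.pixels)
        assert np.array_equal(twice_i.pixels, img.pixels)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_mask_follows_image_coordinate_map(self, seed):
        """A delta mask's hot pixel must land where the affine map sends it."""
        from ricelodging import BandImage, BinaryMask
        rng = np.random.default_rng(seed)
        size = 64
        img = BandImage(np.zeros((size, size, 3), np.uint8), ("R", "G", "B"))
        hot = (int(rng.integers(16, 48)), int(rng.integers(16, 48)))
        mask_px = np.zeros((size, size), np.uint8)
        mask_px[hot] = 1
        tform = draw_affine(rng, (size, size))
        _, out_mask = apply_affine(img, BinaryMask(mask_px), tform)
        # forward-map the source pixel center (x=col, y=row)
        x, y = tform([[hot[1], hot[0]]])[0]
        r, c = int(round(y)), int(round(x))
        if 0 <= r < size and 0 <= c < size:
            hits = np.argwhere(out_mask.pixels)
            assert len(hits) >= 1
            dist = np.abs(hits - np.array([r, c])).sum(axis=1).min()
            assert dist <= 1  # nearest-neighbour rounding tolerance

    def test_random_augment_stays_binary_and_sized(self, small_scene, rng):
        img, mask = small_scene
        out_img, out_mask = augment(img, mask, rng)
        assert out_img.pixels.shape == img.pixels.shape
        assert set(np.unique(out_mask.pixels)) <= {0, 1}


class TestDatasetAssembly:
    def test_split_sizes_follow_floor_rule(self):
        assert split_sizes(5000) == (3500, 750, 750)
        assert split_sizes(20) == (14, 3, 3)
        assert split_sizes(10, (0.7, 0.15, 0.15)) == (8, 1, 1)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="ratios"):
            split_sizes(10, (0.5, 0.5, 0.5))

    def test_build_dataset_partitions_samples(self, small_scene):
        ds = build_dataset([small_scene], n_samples=20, crop_size=64, seed=5)
        split = ds.split
        assert (len(split.train), len(split.val), len(split.test)) == (14, 3, 3)
        assert sorted(split.train + split.val + split.test) == list(range(20))
        assert ds.images.shape == (20, 64, 64, 3)
        assert ds.masks.shape == (20, 64, 64)

    def test_build_dataset_deterministic_under_seed(self, small_scene):
        a = build_dataset([small_scene], n_samples=8, crop_size=48, seed=2)
        b = build_dataset([small_scene], n_samples=8, crop_size=48, seed=2)
        assert np.array_equal(a.images, b.images)
        assert a.split == b.split

    def test_empty_scene_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_dataset([], n_samples=4)

    def test_subset_returns_unit_scaled_nchw(self, small_scene):
        ds = build_dataset([small_scene], n_samples=10, crop_size=48, seed=1)
        x, y = ds.subset("train")
        assert x.shape == (8, 3, 48, 48)  # 7 + the floor remainder
        assert x.dtype == np.float32
        assert 0.0 <= x.min() and x.max() <= 1.0
        assert y.shape == (8, 48, 48)
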