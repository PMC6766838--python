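import logging
import math

import numpy as np
import pytest

from ricelodging import BandImage, build_stack, compute_index
from ricelodging.indices import (MULTISPECTRAL_INDICES, MULTISPECTRAL_TRIPLE,
                                 VISIBLE_INDICES, VISIBLE_TRIPLE)

ALL_INDICES = VISIBLE_INDICES + MULTISPECTRAL_INDICES


def scalar_index(name, R, G, B=None, NIR=None):
    """Independent scalar-arithmetic oracle for every index formula."""
    if name in ("ExG", "ExR", "ExGR"):
        tot = R + G + B
        r, g, b = (0, 0, 0) if tot == 0 else (R / tot, G / tot, B / tot)
        exg = 2 * g - r - b
        exr = 1.4 * r - g
        return {"ExG": exg, "ExR": exr, "ExGR": exg - exr}[name]
    if name == "VDVI":
        den = 2 * G + R + B
        return 0.0 if den == 0 else (2 * G - R - B) / den
    if name == "RGRI":
        return 0.0 if G == 0 else R / G
    if name == "NGRDI":
        return 0.0 if G + R == 0 else (G - R) / (G + R)
    if name == "NDVI":
        return 0.0 if NIR + R == 0 else (NIR - R) / (NIR + R)
    if name == "RVI":
        return 0.0 if R == 0 else NIR / R
    if name == "NDWI":
        return 0.0 if G + NIR == 0 else (G - NIR) / (G + NIR)
    if name == "DVI":
        return NIR - R
    if name == "PVI":
        return (NIR - 10.489 * R - 6.604) / math.sqrt(1 + 10.489 ** 2)
    if name == "SAVI":
        return 1.5 * (NIR - R) / (NIR + R + 0.5)
    raise KeyError(name)


def _image_for(name, rng, size=8):
    names = ("R", "G", "NIR") if name in MULTISPECTRAL_INDICES else ("R", "G", "B")
    px = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
    return BandImage(px, names)


class TestFormulas:
    def test_gray_pixel_nulls_excess_green(self):
        img = BandImage(np.full((1, 1, 3), 100, dtype=np.uint8), ("R", "G", "B"))
        assert compute_index(img, "ExG")[0, 0] == pytest.approx(0.0)

    def test_visible_hand_arithmetic(self):
        img = BandImage(np.array([[[50, 100, 50]]], dtype=np.uint8),
                        ("R", "G", "B"))
        assert compute_index(img, "ExG")[0, 0] == pytest.approx(0.5)
        assert compute_index(img, "NGRDI")[0, 0] == pytest.approx(1 / 3)
        assert compute_index(img, "RGRI")[0, 0] == pytest.approx(0.5)

    def test_nir_equals_red_null_case(self):
        img = BandImage(np.array([[[100, 100, 100]]], dtype=np.uint8),
                        ("R", "G", "NIR"))
        assert compute_index(img, "NDVI")[0, 0] == pytest.approx(0.0)
        assert compute_index(img, "DVI")[0, 0] == pytest.approx(0.0)
        assert compute_index(img, "RVI")[0, 0] == pytest.approx(1.0)

    def test_multispectral_hand_arithmetic(self):
        img = BandImage(np.array([[[50, 100, 150]]], dtype=np.uint8),
                        ("R", "G", "NIR"))
        assert compute_index(img, "NDVI")[0, 0] == pytest.approx(0.5)
        assert compute_index(img, "NDWI")[0, 0] == pytest.approx(-0.2)
        assert compute_index(img, "SAVI")[0, 0] == pytest.approx(
            1.5 * 100 / 200.5, abs=1e-6)

    def test_zero_denominator_yields_zero(self):
        img = BandImage(np.zeros((2, 2, 3), dtype=np.uint8), ("R", "G", "B"))
        for name in ("VDVI", "RGRI", "NGRDI", "ExG"):
            assert np.all(compute_index(img, name) == 0.0)

    def test_unknown_index_rejected(self, rgb_image):
        with pytest.raises(KeyError):
            compute_index(rgb_image, "EVI")

    def test_missing_channel_rejected(self, rgb_image):
        with pytest.raises(KeyError, match="NIR"):
            compute_index(rgb_image, "NDVI")

    @pytest.mark.parametrize("name", ALL_INDICES)
    def test_matches_scalar_loop_oracle(self, name, rng):
        img = _image_for(name, rng)
        got = compute_index(img, name)
        px = img.pixels.astype(float)
        for r in range(img.height):
            for c in range(img.width):
                if "NIR" in img.channel_names:
                    want = scalar_index(name, px[r, c, 0], px[r, c, 1],
                                        NIR=px[r, c, 2])
                else:
                    want = scalar_index(name, px[r, c, 0], px[r, c, 1],
                                        B=px[r, c, 2])
                assert got[r, c] == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("name", ["NDVI", "NGRDI", "NDWI"])
    def test_normalized_differences_bounded(self, name, rng):
        for seed in range(5):
            img = _image_for(name, np.random.default_rng(seed))
            vals = compute_index(img, name)
            assert vals.min() >= -1.0 and vals.max() <= 1.0

    def test_exgr_compositional_identity(self, rgb_image):
        exgr = compute_index(rgb_image, "ExGR")
        diff = compute_index(rgb_image, "ExG") - compute_index(rgb_image, "ExR")
        np.testing.assert_allclose(exgr, diff, rtol=1e-12, atol=1e-12)


class TestStacks:
    def test_rgb_three_stack_names(self, rgb_image):
        stack = build_stack(rgb_image, "three")
        assert stack.index_names == VISIBLE_TRIPLE
        assert stack.depth == 3

    def test_rgn_six_stack_names(self, rgn_image):
        stack = build_stack(rgn_image, "six")
        assert stack.index_names == MULTISPECTRAL_INDICES
        assert stack.depth == 6

    def test_rgn_three_stack_names(self, rgn_image):
        assert build_stack(rgn_image, "three").index_names == MULTISPECTRAL_TRIPLE

    def test_channels_normalized_to_unit_interval(self, rgb_image, rgn_image):
        for img, mode in ((rgb_image, "six"), (rgn_image, "six")):
            stack = build_stack(img, mode)
            assert stack.pixels.min() >= 0.0 and stack.pixels.max() <= 1.0
            for ch in range(stack.depth):
                assert stack.pixels[:, :, ch].min() == pytest.approx(0.0)
                assert stack.pixels[:, :, ch].max() == pytest.approx(1.0)

    def test_minmax_endpoints_two_pixel_image(self):
        # NDVI values {0, 0.5} must map to {0, 1}
        px = np.array([[[100, 0, 100], [50, 0, 150]]], dtype=np.uint8)
        img = BandImage(px, ("R", "G", "NIR"))
        stack = build_stack(img, "three")
        ndvi = stack.pixels[:, :, stack.index_names.index("NDVI")]
        assert sorted(ndvi.ravel().tolist()) == [0.0, 1.0]
        lo, hi = stack.norm_bounds[stack.index_names.index("NDVI")]
        assert (lo, hi) == (0.0, 0.5)

    def test_constant_channel_zeroed_with_warning(self, caplog):
        img = BandImage(np.full((3, 3, 3), 80, dtype=np.uint8), ("R", "G", "NIR"))
        with caplog.at_level(logging.WARNING, logger="ricelodging.indices"):
            stack = build_stack(img, "three")
        assert np.all(stack.pixels == 0.0)
        assert any("constant" in rec.message for rec in caplog.records)

    def test_invalid_mode_rejected(self, rgb_image):
        with pytest.raises(ValueError, match="mode"):
            build_stack(rgb_image, "five")
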