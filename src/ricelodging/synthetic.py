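"""Synthetic paddy-field scenes with known lodged regions.

Real lodging surveys image the canopy from a UAV: standing rice shows a
green, row-textured canopy (and high near-infrared reflectance), while lodged
patches expose stems and ears, appearing brighter and yellower in the
visible bands, darker in NIR, and directionally smeared where the stems lie
flat.  The generator emulates exactly those cues on top of band-limited
texture, an illumination gradient across the frame (tree shadow / sun angle),
and additive sensor noise, and returns the ground-truth lodging mask by
construction.  It makes every downstream stage testable without field
imagery; it does not attempt photorealism.

Scenes are deterministic under their seed.  Lodged area is area-controlled:
a smooth random field (blob bumps + filtered noise) is thresholded at the
quantile matching the requested lodged fraction, so the realized mask
fraction equals the target up to pixel quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, warp

from .raster_io import BandImage, BinaryMask

__all__ = [
    "SceneSpec", "DatasetSplit", "LodgingDataset",
    "generate_scene", "random_crop", "draw_affine", "apply_affine", "augment",
    "build_dataset",
]

# canopy base colors, 0-255 scale
_BASE_RGB = (70.0, 110.0, 55.0)       # green canopy
_BASE_RGN = (70.0, 110.0, 170.0)      # healthy canopy is NIR-bright
# default lodged offsets: brighter/yellower in R, dimmer in G; NIR depressed
_SHIFT_RGB = (60.0, -25.0, 15.0)
_SHIFT_RGN = (60.0, -25.0, -60.0)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic paddy scene.

    row_period is the crop-row texture wavelength in pixels (~11 px matches a
    30 cm row spacing at the 2.6 cm/px ground sampling of a 100 m flight).
    lodged_color_shift is the per-channel additive offset of lodged canopy on
    the 0-255 scale; None selects the variant default.  illumination_gradient
    is the maximum relative shading across the frame (0.25 = 25% darker at
    the far edge).  noise_sigma is the additive Gaussian noise std (0-255
    scale).  Same seed, same spec => bit-identical scene.
    """

    height: int = 960
    width: int = 1280
    target_lodged_fraction: float = 0.3
    n_blobs: int = 6
    row_period: float = 11.0
    lodged_color_shift: tuple[float, ...] | None = None
    smear_length: int = 9
    illumination_gradient: float = 0.25
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_lodged_fraction <= 1.0:
            raise ValueError("target_lodged_fraction must be in [0, 1]")
        if self.height < 1 or self.width < 1:
            raise ValueError("scene must be at least 1x1")
        if self.n_blobs == 0 and self.target_lodged_fraction > 0:
            raise ValueError("n_blobs=0 cannot realize a positive lodged fraction")
        if self.noise_sigma < 0 or self.smear_length < 1:
            raise ValueError("noise_sigma >= 0 and smear_length >= 1 required")


def _lodged_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Blob field thresholded at the quantile hitting the target fraction."""
    h, w = spec.height, spec.width
    frac = spec.target_lodged_fraction
    if frac == 0.0:
        return np.zeros((h, w), dtype=np.uint8)
    if frac == 1.0:
        return np.ones((h, w), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    fld = np.zeros((h, w), dtype=np.float64)
    scale = np.sqrt(h * w * frac / max(spec.n_blobs, 1)) / 1.6
    for _ in range(spec.n_blobs):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        sr = scale * rng.uniform(0.6, 1.6)
        sc = scale * rng.uniform(0.6, 1.6)
        fld = np.maximum(fld, np.exp(-(((rr - r0) / sr) ** 2
                                       + ((cc - c0) / sc) ** 2)))
    # smooth noise wobbles blob boundaries so they are not perfect ellipses
    fld += 0.15 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=min(h, w) / 24)
    thresh = np.quantile(fld, 1.0 - frac)
    return (fld > thresh).astype(np.uint8)


def _motion_kernel(length: int, angle: float) -> np.ndarray:
    """Normalized 1-D line kernel at an angle, for directional smear."""
    length = max(int(length), 1)
    k = np.zeros((length, length), dtype=np.float64)
    t = np.linspace(-(length - 1) / 2, (length - 1) / 2, 4 * length)
    rr = np.clip(np.round(t * np.sin(angle) + (length - 1) / 2), 0, length - 1)
    cc = np.clip(np.round(t * np.cos(angle) + (length - 1) / 2), 0, length - 1)
    k[rr.astype(int), cc.astype(int)] = 1.0
    return k / k.sum()


def generate_scene(spec: SceneSpec,
                   variant: Literal["rgb", "rgn"] = "rgb"
                   ) -> tuple[BandImage, BinaryMask]:
    """Render one scene; returns the image and its ground-truth lodging mask."""
    variant = variant.lower()
    if variant not in ("rgb", "rgn"):
        raise ValueError(f"variant must be 'rgb' or 'rgn', got {variant!r}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = _lodged_mask(spec, rng)

    base = np.array(_BASE_RGB if variant == "rgb" else _BASE_RGN)
    shift = np.array(spec.lodged_color_shift if spec.lodged_color_shift
                     is not None else (_SHIFT_RGB if variant == "rgb"
                                       else _SHIFT_RGN), dtype=np.float64)
    if shift.shape != (3,):
        raise ValueError("lodged_color_shift must have 3 entries")

    rr, cc = np.mgrid[0:h, 0:w]
    row_angle = rng.uniform(-0.15, 0.15)  # rows roughly horizontal
    phase = rng.uniform(0, 2 * np.pi)
    rows = np.sin(2 * np.pi * (rr * np.cos(row_angle) + cc * np.sin(row_angle))
                  / spec.row_period + phase)
    canopy_tex = 10.0 * rows + 8.0 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=1.5)

    # lodged texture: no row pattern, coarser clumps, directional smear
    lodged_tex = 14.0 * ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=2.5)
    kern = _motion_kernel(spec.smear_length, rng.uniform(0, np.pi))
    lodged_tex = ndimage.convolve(lodged_tex, kern, mode="reflect")

    img = np.empty((h, w, 3), dtype=np.float64)
    m = mask.astype(np.float64)
    for ch in range(3):
        canopy = base[ch] + canopy_tex * (1.0 if ch == 1 else 0.6)
        lodged = base[ch] + shift[ch] + lodged_tex
        img[:, :, ch] = canopy * (1 - m) + lodged * m

    if spec.illumination_gradient > 0:
        theta = rng.uniform(0, 2 * np.pi)
        t = (rr * np.sin(theta) + cc * np.cos(theta))
        t = (t - t.min()) / max(t.max() - t.min(), 1.0)
        img *= (1.0 - spec.illumination_gradient * t)[:, :, None]

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    names = ("R", "G", "B") if variant == "rgb" else ("R", "G", "NIR")
    return BandImage(img, names, "8bit"), BinaryMask(mask)


# ---------------------------------------------------------------------------
# crops and augmentation


def random_crop(image, mask: BinaryMask, size: int = 320,
                rng: np.random.Generator | None = None):
    """An aligned random ``size x size`` crop of an image/mask pair.

    ``image`` may be a :class:`BandImage` or an index stack — anything with a
    ``pixels`` dataclass field; the crop keeps the container type.
    """
    rng = rng or np.random.default_rng()
    h, w = image.pixels.shape[:2]
    if mask.shape != (h, w):
        raise ValueError("image and mask sizes differ")
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}")
    r0 = int(rng.integers(0, h - size + 1))
    c0 = int(rng.integers(0, w - size + 1))
    return (
        replace(image, pixels=image.pixels[r0:r0 + size, c0:c0 + size].copy()),
        BinaryMask(mask.pixels[r0:r0 + size, c0:c0 + size].copy()),
    )


def draw_affine(rng: np.random.Generator, shape: tuple[int, int],
                max_rotation: float = 30.0, scale_range=(0.8, 1.2),
                max_shear: float = 10.0, max_skew: float = 10.0
                ) -> AffineTransform:
    """Draw one random geometric augmentation about the image center.

    The transform composes horizontal/vertical flips (p=0.5 each), rotation
    within +/-max_rotation degrees, isotropic scaling, shear along x and skew
    (shear along y) within +/-max_shear / max_skew degrees.  Angle bounds are
    mild so lodged regions stay in frame.
    """
    h, w = shape
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    ang = np.deg2rad(rng.uniform(-max_rotation, max_rotation))
    sc = rng.uniform(*scale_range)
    shx = np.deg2rad(rng.uniform(-max_shear, max_shear))
    shy = np.deg2rad(rng.uniform(-max_skew, max_skew))

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    flip = np.diag([-1.0 if flip_h else 1.0, -1.0 if flip_v else 1.0, 1.0])
    core = (AffineTransform(rotation=ang).params
            @ np.array([[1, np.tan(shx), 0], [np.tan(shy), 1, 0], [0, 0, 1]])
            @ np.diag([sc, sc, 1.0]) @ flip)
    to_center = AffineTransform(translation=-center).params
    back = AffineTransform(translation=center).params
    return AffineTransform(matrix=back @ core @ to_center)


def apply_affine(image: BandImage, mask: BinaryMask, tform: AffineTransform
                 ) -> tuple[BandImage, BinaryMask]:
    """Apply one affine transform to both members of an aligned pair.

    Image pixels are bilinearly interpolated, the mask nearest-neighbour
    resampled so it stays binary.  Both use reflected borders: out-of-frame
    regions show mirrored scene content, so they must carry the mirrored
    labels as well — filling the mask with background zeros instead would
    label reflected lodged texture as non-lodged and corrupt the training
    signal.  Output size equals input size; the image container type
    (:class:`BandImage` or index stack) is preserved.
    """
    eight_bit = getattr(image, "value_scale", None) == "8bit"
    img = image.as_unit() if hasattr(image, "as_unit") \
        else np.asarray(image.pixels, dtype=np.float32)
    out = np.stack([
        warp(img[:, :, ch], tform.inverse, order=1, mode="reflect",
             preserve_range=True)
        for ch in range(img.shape[2])], axis=2)
    wmask = warp(mask.pixels.astype(np.float32), tform.inverse, order=0,
                 mode="reflect", preserve_range=True)
    if eight_bit:
        out_px = np.clip(np.round(out * 255), 0, 255).astype(np.uint8)
    else:
        out_px = np.clip(out, 0, 1).astype(np.float32)
    return replace(image, pixels=out_px), BinaryMask((wmask > 0.5).astype(np.uint8))


def augment(image, mask: BinaryMask, rng: np.random.Generator):
    """Randomly flip/rotate/scale/shear/skew an aligned image/mask pair."""
    tform = draw_affine(rng, mask.shape)
    return apply_affine(image, mask, tform)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test sample indices partitioning a dataset."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def __post_init__(self) -> None:
        all_ids = sorted(self.train + self.val + self.test)
        if all_ids != list(range(len(all_ids))):
            raise ValueError("split must partition 0..n-1 exactly once")

    @property
    def n_samples(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)


def split_sizes(n: int, ratios=(0.7, 0.15, 0.15)) -> tuple[int, int, int]:
    """Floor-partition n into train/val/test; the remainder goes to train."""
    if len(ratios) != 3 or any(r < 0 for r in ratios) or \
            abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be 3 nonnegative values summing to 1: {ratios}")
    n_train = int(np.floor(n * ratios[0]))
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))
    n_train += n - (n_train + n_val + n_test)
    return n_train, n_val, n_test


@dataclass
class LodgingDataset:
    """Augmented crops with their masks and a train/val/test split.

    Images are stored channels-last on their native scale (uint8 for 8-bit
    imagery, float32 in [0, 1] for index stacks); :meth:`subset` returns
    network-ready float32 NCHW arrays.
    """

    images: np.ndarray          # (n, size, size, C)
    masks: np.ndarray           # (n, size, size) uint8
    split: DatasetSplit
    channel_names: tuple[str, ...] = ()

    @property
    def n_channels(self) -> int:
        return self.images.shape[3]

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        ids = list(getattr(self.split, which))
        imgs = self.images[ids].astype(np.float32)
        if self.images.dtype == np.uint8:
            imgs /= 255.0
        return imgs.transpose(0, 3, 1, 2), self.masks[ids]


def build_dataset(scene_pairs: Sequence[tuple[BandImage, BinaryMask]],
                  n_samples: int = 5000, crop_size: int = 320,
                  ratios=(0.7, 0.15, 0.15), seed: int = 0,
                  augment_crops: bool = True) -> LodgingDataset:
    """Cut random crops from scenes, augment them, and split 0.7/0.15/0.15.

    Crops are drawn from the scenes round-robin (overlapping windows), each
    independently augmented, then randomly partitioned with floor-sized val
    and test subsets and the remainder in train.  Deterministic under seed.
    """
    if not scene_pairs:
        raise ValueError("need at least one scene pair")
    n_tr, n_va, n_te = split_sizes(n_samples, ratios)
    ss = np.random.SeedSequence(seed)
    crop_rng, aug_rng, split_rng = (np.random.default_rng(s)
                                    for s in ss.spawn(3))
    images, masks = [], []
    first = scene_pairs[0][0]
    names = tuple(getattr(first, "channel_names", None)
                  or getattr(first, "index_names", ()))
    for i in range(n_samples):
        img, msk = scene_pairs[i % len(scene_pairs)]
        cimg, cmsk = random_crop(img, msk, crop_size, crop_rng)
        if augment_crops:
            cimg, cmsk = augment(cimg, cmsk, aug_rng)
        images.append(cimg.pixels)
        masks.append(cmsk.pixels)
    perm = split_rng.permutation(n_samples)
    split = DatasetSplit(
        train=tuple(int(i) for i in perm[:n_tr]),
        val=tuple(int(i) for i in perm[n_tr:n_tr + n_va]),
        test=tuple(int(i) for i in perm[n_tr + n_va:]),
        ratios=tuple(ratios),
    )
    return LodgingDataset(np.stack(images), np.stack(masks), split, names)
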