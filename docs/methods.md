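# Methods

## Problem and model

Lodging — the permanent displacement of rice stems from vertical by wind or
rain — shows up in UAV canopy imagery as brighter, yellower, directionally
smeared patches against the green, row-textured standing canopy, and as
depressed near-infrared reflectance where healthy canopy would be bright.
The package treats lodging mapping as binary semantic segmentation: a UNet
encoder–decoder predicts a per-pixel lodging probability from 3-band imagery
(RGB or R/G/NIR) or from stacks of vegetation indices derived from it.

The network is the classic 4-level UNet with equal-size skip concatenation:
every block is (3×3 convolution, padding 1 → batch normalization → ReLU) ×2;
the encoder doubles channels at each of four 2×2 max-pool stages
(64→128→256→512→1024 at the default base width), so a 320×320 input reaches a
20×20×1024 bottleneck; the decoder mirrors the encoder with 2×2-stride
transposed convolutions, concatenating each encoder feature map to its
decoder counterpart; a final 1×1 convolution produces a single logit per
pixel, and its sigmoid the lodging probability.  Because the padded
convolutions preserve spatial size, skips need no cropping, and the network
is fully convolutional: any input whose sides are multiples of 2⁴ = 16 is
admissible.

Training minimizes mean per-pixel binary cross-entropy with Adam
(conventional β₁=0.9, β₂=0.999, ε=1e-8), initial learning rate 5e-4 halved
every 10 epochs, mini-batch 12, with Xavier-uniform weight initialization
(variance 2/(fan_in+fan_out)).  Loss and dice are recorded on the training
and validation sets each epoch, and the checkpoint with the highest
validation dice is the final model (ties keep the earlier epoch; no early
stopping).  The evaluation metric throughout is the dice coefficient
2|R_seg ∩ R_gt| / (|R_seg| + |R_gt|), computed on outputs thresholded at
0.5; two empty masks score 1 by convention.

The single-channel sigmoid head makes the "cross entropy" loss the binary
form; a two-class softmax would contradict the one-channel output.  The
output convolution is 1×1 (kernel size of the head is an open choice; 1×1 is
assumed and stated here rather than silently standardized).

## Implementation of the network

The layers (convolution via im2col + BLAS matmul, batch normalization,
max-pooling, 2×2-stride transposed convolution), the Adam optimizer, and
full backpropagation are implemented in NumPy inside `ricelodging.nn`.
Convolutions process output rows in strips sized to cap the im2col scratch
buffer (~190 MB), so a 1280×1280 tile runs through the full-width network in
bounded memory; column buffers are rebuilt during the backward pass instead
of cached.  Every layer's analytic gradient is verified against central
differences in float64 in the test suite; arithmetic is float32 elsewhere.
Checkpoints are self-describing `.npz` files (weights + batch-norm running
statistics + architecture config) and round-trip bit-exactly.

## Whole-scene inference and assessment

Mosaics are traversed with non-overlapping 1280×1280 windows (stride =
window; the traversal-and-discard scheme implies no blending, and border
artifacts are accepted as part of the method).  Edge windows are zero-filled
— after scaling to the unit interval, so the fill is the normalized zero —
and the padded part of the prediction is discarded.  The stitched
probability map is binarized with a strict threshold: probability > 0.5 is
lodged, exactly 0.5 is not.

Damage assessment rasterizes one or more user-drawn polygons ("marks") with
pixel-center containment and reports the lodging ratio
100·|pred ∧ mark| / |mark| to two decimals.  Polygon vertices are
(row, col) in pixel-corner coordinates — the pixel at index (r, c) covers
[r, r+1) × [c, c+1) with its center at (r+0.5, c+0.5) — and pixel centers
exactly on the boundary are excluded.  Multiple disjoint polygons are
assessed as their union.

## Vegetation indices

Twelve indices in two families (see `ricelodging.indices` for formulas):
visible ExG, ExR, VDVI, RGRI, NGRDI, ExGR and multispectral NDVI, RVI, NDWI,
DVI, PVI, SAVI.  ExG/ExR/ExGR use chromatic coordinates r = R/(R+G+B) etc.,
the rest raw band values, following the usual definitions of their sources;
ExR is 1.4r − g in the normalized form of Meyer's definition.  PVI uses the
soil-line coefficients a = 10.489, b = 6.604; SAVI the soil-adjustment
factor L = 0.5.  Zero-denominator pixels yield 0 rather than NaN so stacked
network inputs stay finite.  Network input stacks are depth 3 (ExG, ExR,
VDVI or NDVI, RVI, NDWI) or depth 6 (the full family), each channel min–max
normalized to [0, 1] per image — unbounded indices (RVI, DVI, PVI) need the
rescaling for stable optimization — with the bounds recorded alongside.

## Synthetic scenes: what they emulate, what they do not

No suitable public UAV lodging imagery ships with the package, so the
generator in `ricelodging.synthetic` produces scenes with ground truth known
by construction.  It emulates the cues a segmenter actually uses: sinusoidal
crop-row texture (default wavelength 11 px, matching ~30 cm row spacing at
~2.6 cm/px from a 100 m flight) on a green canopy; lodged patches as smooth
random blobs, brighter in red (default +60 on the 0–255 scale), dimmer in
green (−25), NIR-depressed (−60) in the R/G/NIR variant, with band-limited
texture directionally smeared over ~9 px; a linear illumination gradient
across the frame (default 25% shading, emulating uneven illumination such as
tree shadow); and additive Gaussian sensor noise (default σ = 5).  Lodged
area is area-controlled: the blob field is thresholded at the quantile
matching the requested lodged fraction, so the realized fraction equals the
target up to pixel quantization.  Scenes are bit-reproducible under their
seed.

Not emulated: perspective and stitching artifacts, vignetting and BRDF,
mixed growth stages, soil/water background between rows, partially lodged
(leaning) canopy, and the label noise of manual annotation.  Passing the
end-to-end tests therefore demonstrates that the pipeline — data handling,
optimization, inference, assessment — is correct and can learn separable
canopy classes; it does not certify field accuracy on real imagery, where
class contrast is weaker and annotation imperfect.

## Dataset pipeline

Training samples are random (overlapping) crops from the scenes, taken
round-robin, each independently augmented by a random affine: horizontal and
vertical flips (p = 0.5 each), rotation ±30°, isotropic scale 0.8–1.2, shear
and skew ±10° — mild ranges that keep lodged regions in frame.  Images are
bilinearly resampled and masks nearest-neighbour resampled (so they stay
binary) under the same transform; both use reflected borders.  Reflecting
the mask together with the image is deliberate: out-of-frame regions show
mirrored scene content, and giving them background-zero labels instead would
mark reflected lodged texture as non-lodged — a label-noise ceiling that
measurably caps attainable dice.  Samples are split 0.7/0.15/0.15 into
train/validation/test with floor-sized validation and test subsets and the
remainder in train (5000 → 3500/750/750); the split, crop, augmentation and
weight-initialization streams all derive independently from one seed, so
changing one stage's consumption does not perturb the others.

## Scaled experiment sizes

The canned end-to-end experiment (`ricelodging.experiments`, also run by
`scripts/acceptance.py`) uses sizes chosen for a single CPU with the NumPy
engine: 960×1280 scenes, 200 crops of 160×160 (140/30/30 after the split), a
base-16 network (~1.9 M parameters), 8 epochs at batch 12.  The task is the
generator's high-contrast setting (red shift +90, noise σ = 4, 55% lodged
area).  Training and the held-out scene use different seeds of the same
scene process.  The held-out scene is segmented through the standard
1280-window tiling path and assessed inside a fixed quadrilateral mark
covering most of the field; the reported error is |predicted − true|
lodging ratio in percentage points.  The micro determinism pipeline
(320×480 scene, 24 crops of 96×96, base-8 net, 2 epochs) exists only to
check that two identically seeded generate→train→predict→assess runs give
byte-identical reports.

## Numerical choices and degenerate inputs

- Dice of two empty masks: 1 (perfect agreement convention).
- Strict ">" at the 0.5 threshold; a probability of exactly 0.5 is
  non-lodged.
- Min–max normalization of a constant index channel would divide by zero;
  the channel is zeroed and a warning logged.
- Batch-norm running variance uses the unbiased batch estimate with
  momentum 0.1, eps 1e-5.
- Mask values outside {0, 1} and polygons with fewer than 3 distinct or
  self-intersecting/collinear vertices are rejected at construction.
- Inputs whose sides are not multiples of 16 raise a shape error rather
  than being silently cropped; whole scenes of any size go through the
  tiling path instead.
- BCE is computed in the log-sum-exp form, stable for arbitrarily large
  logits.

## Known limitations

Pure-NumPy training is orders of magnitude slower than a GPU framework;
the defaults of `TrainConfig` (100 epochs) and full-width `NetConfig`
(base 64) describe the full protocol, while the shipped experiments run the
reduced sizes above.  Stride-equals-window tiling can leave visible seams at
tile borders on real mosaics.  Per-image min–max normalization of index
stacks makes predictions depend on each image's own extrema; radiometric
calibration is out of scope, as are orthomosaic stitching and RAW decoding.
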