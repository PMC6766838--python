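# ricelodging

Mapping lodged rice in UAV canopy imagery and turning the map into a damage
number.  Lodging — stems flattened by wind and rain — cuts yield and
complicates harvest; surveys that walk the paddy are slow and damage the
crop, while a drone flying ~100 m photographs hectares in minutes.  This
package segments lodged area in those images with a UNet and reports, for a
surveyor-marked field polygon, the *lodging ratio*: the percentage of the
field that is down — the quantity an agronomist or insurance assessor
actually needs.

It is written for agricultural remote-sensing practitioners and for anyone
who wants a fully inspectable segmentation pipeline: the UNet, its
backpropagation, Adam, and batch normalization are implemented in NumPy
inside the package (`ricelodging.nn`), with every layer's gradient checked
against finite differences in the test suite.

## The method

- **Inputs.** 3-band rasters: RGB from a digital camera or R/G/NIR from a
  multispectral camera — or stacks of 3/6 vegetation indices (ExG, ExR,
  VDVI, …, NDVI, RVI, NDWI, …) computed from them.
- **Network.** A 4-level UNet: (Conv3×3 → BN → ReLU)×2 blocks, channels
  64→128→256→512→1024 down the encoder (a 320×320 input reaches a
  20×20×1024 bottleneck), transposed-convolution upsampling with skip
  concatenation, a 1×1 single-channel sigmoid head.
- **Training.** Adam on binary cross-entropy, lr 5·10⁻⁴ halved every 10
  epochs, batch 12, Xavier initialization; the epoch with the best
  validation dice supplies the final weights.  The metric is the dice
  coefficient, dice = 2|R_seg ∩ R_gt| / (|R_seg| + |R_gt|).
- **Whole scenes.** Large mosaics are segmented in non-overlapping
  1280×1280 sliding windows, zero-filled at the edges, thresholded at 0.5
  (strictly greater = lodged).
- **Assessment.** lodging ratio = 100 · |prediction ∧ mark| / |mark| for a
  polygon mark rasterized by pixel-center containment.

Because suitable UAV imagery cannot ship with the package, a synthetic
scene generator (`ricelodging.synthetic`) renders paddy scenes — row-textured
canopy, brighter/yellower directionally-smeared lodged patches, NIR
depression, illumination gradients, sensor noise — with ground truth known
by construction.  See `docs/methods.md` for what it does and does not
emulate.

## Worked example

```python
from ricelodging import (LodgingSegmentationModel, NetConfig, TrainConfig,
                         PolygonMark, SceneSpec, TileSpec, generate_scene,
                         lodging_ratio, scene_dice)

# two independent scenes of the same process: train on one, assess the other
spec = lambda seed: SceneSpec(height=960, width=1280,
                              target_lodged_fraction=0.55, n_blobs=5,
                              lodged_color_shift=(90, -40, 20),
                              illumination_gradient=0.15, noise_sigma=4,
                              seed=seed)
train_scene = generate_scene(spec(11), "rgb")
field_img, field_truth = generate_scene(spec(99), "rgb")

model = LodgingSegmentationModel.from_scenes(
    [train_scene], n_samples=200, crop_size=160,
    net_config=NetConfig(in_channels=3, base_channels=16),
    train_config=TrainConfig(epochs=8, batch_size=12, seed=0), seed=1)
res = model.fit(verbose=True)
print(res.summary())

prob, pred = res.predict_scene(field_img, TileSpec())
mark = PolygonMark([(60, 80), (110, 1200), (900, 1150), (860, 50)])
print("scene dice", round(scene_dice(pred, field_truth), 4))
print(lodging_ratio(pred, mark, field_id="demo").to_json())
print(lodging_ratio(field_truth, mark, field_id="demo-truth").to_json())
```

The equivalent canned experiment (`ricelodging.experiments.
run_scaled_experiment`, seed 1) prints per-epoch progress ending in

```
epoch   7  lr 5.00e-04  train loss 0.1192 dice 0.8810  val loss 0.1223 dice 0.9650
```

and returns

```json
{
 "n_train_crops": 140, "crop_size": 160, "best_epoch": 7,
 "val_dice": 0.9650, "test_dice": 0.9997, "scene_dice": 0.9995,
 "lodging_ratio_true": 61.19, "lodging_ratio_pred": 61.18,
 "lodging_ratio_error_pp": 0.01
}
```

Reading: after 8 epochs on 140 crops the best-validation model segments the
held-out test crops with dice ≈ 0.97–1.00 and the never-seen 960×1280 scene
with dice ≈ 0.999 through the tiling path, and the assessed lodging
percentage inside the polygon differs from the ground-truth percentage by
0.01 points — i.e. the damage number, the end product, is recovered almost
exactly on a scene where the truth is known.

The same pipeline is available from the shell:

```bash
ricelodging generate --n-scenes 3 --lodged-fraction 0.55 --seed 1 --out data/
ricelodging train --data data/ --epochs 8 --base-channels 16 \
    --n-samples 200 --crop-size 160 --seed 1 --out run/
ricelodging predict --model run/best.npz --image data/images/scene_002.png \
    --out-mask pred.png
ricelodging assess --mask pred.png --mark mark.json --out report.json
```

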