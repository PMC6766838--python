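"""Canned end-to-end experiments on synthetic scenes.

These wire the full pipeline — scene generation, crop/augment/split, UNet
training, sliding-window scene prediction, and polygon damage assessment —
at sizes a single CPU handles in minutes.  The scaled experiment trains a
reduced-width network (base 16) on 200 crops of 160 x 160 from one
high-contrast scene with 55% lodged area, then segments a held-out scene and
recovers its lodging ratio inside a marked polygon; the micro pipeline is a
seconds-scale version used to check run-to-run determinism.
"""

from __future__ import annotations

import json

import numpy as np

from .assess import lodging_ratio
from .model import LodgingSegmentationModel
from .raster_io import PolygonMark
from .synthetic import SceneSpec, generate_scene
from .tiling import TileSpec, predict_scene, scene_dice
from .training import TrainConfig
from .unet import NetConfig

__all__ = ["easy_scene_spec", "run_scaled_experiment", "run_micro_pipeline"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent derived streams so stages do not perturb each other."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def easy_scene_spec(seed: int, height: int = 960, width: int = 1280,
                    lodged_fraction: float = 0.55) -> SceneSpec:
    """A high-contrast, low-noise scene: clearly separable lodged patches."""
    return SceneSpec(
        height=height, width=width,
        target_lodged_fraction=lodged_fraction, n_blobs=5,
        lodged_color_shift=(90.0, -40.0, 20.0),
        illumination_gradient=0.15, noise_sigma=4.0, seed=seed)


def run_scaled_experiment(seed: int = 0, verbose: bool = False) -> dict:
    """Train on one easy scene, assess a held-out scene of the same process.

    Returns the quantities the pipeline computes: best validation dice, mean
    test-subset dice, whole-scene dice on the held-out scene, and the true
    vs predicted lodging ratio (percent) inside a fixed polygon mark.
    """
    s_train, s_holdout, s_data, s_fit = _child_seeds(seed, 4)

    train_scene = generate_scene(easy_scene_spec(s_train), "rgb")
    holdout_img, holdout_gt = generate_scene(easy_scene_spec(s_holdout), "rgb")

    model = LodgingSegmentationModel.from_scenes(
        [train_scene], n_samples=200, crop_size=160,
        net_config=NetConfig(in_channels=3, base_channels=16),
        train_config=TrainConfig(epochs=8, batch_size=12, seed=s_fit),
        seed=s_data)
    res = model.fit(verbose=verbose)

    test_loss, test_dice = res.evaluate("test")
    prob, pred = res.predict_scene(holdout_img, TileSpec())
    sdice = scene_dice(pred, holdout_gt)

    mark = PolygonMark([(60, 80), (110, 1200), (900, 1150), (860, 50)])
    rep_pred = lodging_ratio(pred, mark, field_id="holdout")
    rep_true = lodging_ratio(holdout_gt, mark, field_id="holdout")

    return {
        "n_train_crops": len(model.dataset.split.train),
        "crop_size": 160,
        "best_epoch": res.best_epoch,
        "val_dice": res.best_val_dice,
        "test_loss": test_loss,
        "test_dice": test_dice,
        "scene_dice": sdice,
        "lodging_ratio_true": rep_true.lodging_ratio,
        "lodging_ratio_pred": rep_pred.lodging_ratio,
        "lodging_ratio_error_pp": round(
            abs(rep_pred.lodging_ratio - rep_true.lodging_ratio), 2),
    }


def run_micro_pipeline(seed: int = 0) -> str:
    """Generate -> train -> predict -> assess at toy scale; JSON report.

    Small enough to run twice in seconds; two calls with the same seed must
    produce byte-identical reports.
    """
    s_scene, s_data, s_fit = _child_seeds(seed, 3)
    spec = easy_scene_spec(s_scene, height=320, width=480)
    scene = generate_scene(spec, "rgb")
    model = LodgingSegmentationModel.from_scenes(
        [scene], n_samples=24, crop_size=96,
        net_config=NetConfig(in_channels=3, base_channels=8),
        train_config=TrainConfig(epochs=2, batch_size=12, seed=s_fit),
        seed=s_data)
    res = model.fit()
    prob, pred = res.predict_scene(scene[0], TileSpec(window=320))
    mark = PolygonMark([(20, 20), (20, 460), (300, 460), (300, 20)])
    report = lodging_ratio(pred, mark, field_id="micro")
    payload = {
        "best_epoch": res.best_epoch,
        "val_dice": round(res.best_val_dice, 6),
        "scene_dice": round(scene_dice(pred, scene[1]), 6),
        "assessment": json.loads(report.to_json()),
    }
    return json.dumps(payload, sort_keys=True)
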