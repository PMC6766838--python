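"""Model / Results interface for lodging segmentation.

``LodgingSegmentationModel`` holds the data (a :class:`LodgingDataset`) and
the architecture/optimization configuration; ``fit()`` runs the training
protocol and returns a :class:`SegmentationResults` carrying the selected
network, the per-epoch history, evaluation helpers, whole-scene prediction,
and damage assessment.

>>> model = LodgingSegmentationModel(dataset,
...                                  net_config=NetConfig(in_channels=3))
>>> res = model.fit()
>>> print(res.summary())
>>> loss, d = res.evaluate("test")
>>> prob, mask = res.predict_scene(scene_image)
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Sequence

import numpy as np

from . import training
from .assess import AssessmentReport, lodging_ratio
from .raster_io import BinaryMask, PolygonMark
from .synthetic import LodgingDataset, build_dataset
from .tiling import TileSpec, predict_scene
from .training import TrainConfig, TrainLog
from .unet import NetConfig, UNet, load_checkpoint, save_checkpoint

__all__ = ["LodgingSegmentationModel", "SegmentationResults"]


class LodgingSegmentationModel:
    """A UNet lodging segmenter bound to a dataset, ready to fit."""

    def __init__(self, dataset: LodgingDataset,
                 net_config: NetConfig | None = None,
                 train_config: TrainConfig | None = None) -> None:
        self.dataset = dataset
        self.net_config = net_config or NetConfig(
            in_channels=dataset.n_channels)
        self.train_config = train_config or TrainConfig()
        if self.net_config.in_channels != dataset.n_channels:
            raise ValueError(
                f"net expects {self.net_config.in_channels} channels, dataset "
                f"has {dataset.n_channels}")

    @classmethod
    def from_scenes(cls, scene_pairs: Sequence[tuple],
                    n_samples: int = 5000, crop_size: int = 320,
                    net_config: NetConfig | None = None,
                    train_config: TrainConfig | None = None,
                    seed: int = 0) -> "LodgingSegmentationModel":
        """Build the crop/augment/split dataset from scenes, then the model."""
        dataset = build_dataset(scene_pairs, n_samples=n_samples,
                                crop_size=crop_size, seed=seed)
        return cls(dataset, net_config, train_config)

    def fit(self, verbose: bool = False,
            callback=None) -> "SegmentationResults":
        """Train under the configured protocol; returns the results object."""
        net = UNet(self.net_config, seed=self.train_config.seed)
        best_net, log = training.train(net, self.dataset, self.train_config,
                                       verbose=verbose, callback=callback)
        return SegmentationResults(self, best_net, log)


class SegmentationResults:
    """Fitted segmenter: best-validation weights plus training diagnostics."""

    def __init__(self, model: LodgingSegmentationModel | None, net: UNet,
                 log: TrainLog) -> None:
        self.model = model
        self.net = net
        self.log = log

    @property
    def best_epoch(self) -> int:
        return self.log.best_epoch

    @property
    def best_val_dice(self) -> float:
        return self.log.best_val_dice

    def evaluate(self, subset: str = "test") -> tuple[float, float]:
        """(mean loss, mean dice) over a split subset of the bound dataset."""
        if self.model is None:
            raise ValueError("results were loaded without a dataset")
        x, y = self.model.dataset.subset(subset)
        return training.evaluate(self.net, x, y,
                                 self.model.train_config.batch_size)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probability maps for a float32 NCHW batch."""
        return self.net.forward(x, train=False)

    def predict_scene(self, image, tile_spec: TileSpec = TileSpec()
                      ) -> tuple[np.ndarray, BinaryMask]:
        """Sliding-window segmentation of a whole scene."""
        return predict_scene(self.net, image, tile_spec)

    def assess(self, image, marks: PolygonMark | Sequence[PolygonMark],
               tile_spec: TileSpec = TileSpec(),
               field_id: str = "field") -> AssessmentReport:
        """Segment a scene and report the lodging ratio inside the mark."""
        _, mask = self.predict_scene(image, tile_spec)
        return lodging_ratio(mask, marks, field_id=field_id)

    def summary(self) -> str:
        """A plain-text summary of the fit."""
        cfg = self.net.config
        lines = [
            "Lodging segmentation fit",
            "=" * 46,
            f"architecture     UNet {cfg.in_channels}->"
            + "->".join(str(c) for c in cfg.encoder_channels)
            + f" (base {cfg.base_channels}, {cfg.levels} levels)",
            f"parameters       {self.net.n_parameters():,}",
            f"epochs run       {self.log.n_epochs}",
            f"best epoch       {self.best_epoch}",
            f"best val dice    {self.best_val_dice:.4f}",
            f"val loss there   {self.log.val_loss[self.best_epoch]:.4f}",
            f"final train dice {self.log.train_dice[-1]:.4f}",
        ]
        if self.model is not None:
            tc = self.model.train_config
            sp = self.model.dataset.split
            lines += [
                f"optimizer        Adam, lr {tc.initial_lr:g} halved every "
                f"{tc.lr_halving_period} epochs, batch {tc.batch_size}",
                f"samples          {sp.n_samples} "
                f"({len(sp.train)}/{len(sp.val)}/{len(sp.test)} "
                "train/val/test)",
            ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        return self.log.plot(ax=ax)

    def save(self, path) -> None:
        """Checkpoint the selected weights with the fit metadata."""
        extra = {"log": {k: getattr(self.log, k) for k in
                         ("train_loss", "train_dice", "val_loss", "val_dice",
                          "lr", "best_epoch")}}
        if self.model is not None:
            extra["train_config"] = asdict(self.model.train_config)
        save_checkpoint(path, self.net, epoch=self.best_epoch, extra=extra)

    @classmethod
    def load(cls, path) -> "SegmentationResults":
        """Restore a saved results object (without its dataset)."""
        net, header = load_checkpoint(path)
        log = TrainLog()
        for key, val in header.get("extra", {}).get("log", {}).items():
            setattr(log, key, val)
        return cls(None, net, log)
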