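"""Training loop, dice metric, and learning-rate schedule.

The protocol: Adam on mean per-pixel binary cross-entropy, initial learning
rate 5e-4 halved every 10 epochs, mini-batch 12, 100 epochs, with loss and
dice recorded on the training and validation sets at the end of every epoch
and the checkpoint with the best validation dice kept as the final model.
Dice is always computed on outputs thresholded at 0.5, matching the
whole-scene inference rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, bce_with_logits, bce_with_logits_per_sample, sigmoid
from .raster_io import BinaryMask
from .synthetic import LodgingDataset
from .unet import UNet

__all__ = ["TrainConfig", "TrainLog", "dice", "lr_at_epoch", "train", "evaluate"]

THRESHOLD = 0.5


def dice(seg, gt) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) between two binary masks.

    Ranges from 0 (disjoint) to 1 (identical); equals the F1 score of the
    pixelwise classification.  Two empty masks are in perfect agreement, so
    that case returns 1.
    """
    a = seg.pixels if isinstance(seg, BinaryMask) else np.asarray(seg)
    b = gt.pixels if isinstance(gt, BinaryMask) else np.asarray(gt)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the protocol above)."""

    initial_lr: float = 5e-4
    lr_halving_period: int = 10
    batch_size: int = 12
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.batch_size < 1 or self.epochs < 1 \
                or self.lr_halving_period < 1:
            raise ValueError("TrainConfig values must be positive")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stepped schedule: initial_lr / 2^(epoch // halving_period)."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.initial_lr / 2 ** (epoch // config.lr_halving_period)


@dataclass
class TrainLog:
    """Per-epoch history plus the best-validation bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.val_dice)

    @property
    def best_val_dice(self) -> float:
        return self.val_dice[self.best_epoch]

    def to_table(self) -> str:
        """The history as a tab-separated table (one row per epoch)."""
        lines = ["epoch\tlr\ttrain_loss\ttrain_dice\tval_loss\tval_dice"]
        for e in range(self.n_epochs):
            lines.append(
                f"{e}\t{self.lr[e]:.3e}\t{self.train_loss[e]:.6f}\t"
                f"{self.train_dice[e]:.6f}\t{self.val_loss[e]:.6f}\t"
                f"{self.val_dice[e]:.6f}")
        return "\n".join(lines) + "\n"

    def plot(self, ax=None):
        """Loss and dice learning curves on twin axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        epochs = np.arange(self.n_epochs)
        ax.plot(epochs, self.train_loss, "C0-", label="train loss")
        ax.plot(epochs, self.val_loss, "C0--", label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("BCE loss", color="C0")
        ax2 = ax.twinx()
        ax2.plot(epochs, self.train_dice, "C1-", label="train dice")
        ax2.plot(epochs, self.val_dice, "C1--", label="val dice")
        ax2.set_ylabel("dice", color="C1")
        ax2.axvline(self.best_epoch, color="k", lw=0.8, ls=":")
        ax.figure.legend(loc="lower right", fontsize=8)
        return ax


def _batches(n: int, batch_size: int, order=None):
    idx = np.arange(n) if order is None else order
    for s in range(0, n, batch_size):
        yield idx[s:s + batch_size]


def evaluate(net: UNet, images: np.ndarray, masks: np.ndarray,
             batch_size: int = 12) -> tuple[float, float]:
    """Mean per-sample loss and thresholded dice over a subset.

    ``images`` is float32 NCHW, ``masks`` (N, H, W) binary.  Batch
    normalization uses running statistics (eval mode); the mean is unweighted
    across samples.
    """
    if len(images) == 0:
        raise ValueError("cannot evaluate an empty subset")
    losses, dices = [], []
    for ids in _batches(len(images), batch_size):
        logits = net.forward_logits(images[ids], train=False)
        y = masks[ids][:, None].astype(np.float32)
        losses.extend(bce_with_logits_per_sample(logits, y).tolist())
        probs = sigmoid(logits)
        for k in range(len(ids)):
            dices.append(dice(probs[k, 0] > THRESHOLD, masks[ids[k]] > 0))
    return float(np.mean(losses)), float(np.mean(dices))


def train(net: UNet, dataset: LodgingDataset, config: TrainConfig,
          verbose: bool = False, callback=None) -> tuple[UNet, TrainLog]:
    """Fit the network; returns the best-validation model and the history.

    Each epoch shuffles the training subset, steps Adam on every mini-batch
    at the scheduled learning rate, then evaluates the validation subset in
    eval mode.  The returned network carries the weights of the epoch with
    the highest validation dice (earliest epoch on ties).  Deterministic
    under ``config.seed`` with a fixed BLAS thread count.
    """
    if not dataset.split.train or not dataset.split.val:
        raise ValueError("train and val subsets must be nonempty")
    if dataset.n_channels != net.config.in_channels:
        raise ValueError(
            f"dataset has {dataset.n_channels} channels but network expects "
            f"{net.config.in_channels}")
    rng = np.random.default_rng(config.seed)
    x_tr, y_tr = dataset.subset("train")
    x_va, y_va = dataset.subset("val")
    opt = Adam()
    log = TrainLog()
    best_state = None
    best_dice = -1.0

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(len(x_tr))
        ep_losses, ep_dices, ep_sizes = [], [], []
        for ids in _batches(len(x_tr), config.batch_size, order):
            xb = x_tr[ids]
            yb = y_tr[ids][:, None].astype(np.float32)
            logits = net.forward_logits(xb, train=True)
            loss, dlogits = bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            net.backward(dlogits)
            opt.step(net.named_params(), net.named_grads(), lr)
            probs = sigmoid(logits)
            batch_dice = np.mean([
                dice(probs[k, 0] > THRESHOLD, yb[k, 0] > 0.5)
                for k in range(len(ids))])
            ep_losses.append(loss)
            ep_dices.append(float(batch_dice))
            ep_sizes.append(len(ids))
        wts = np.asarray(ep_sizes, dtype=float)
        log.train_loss.append(float(np.average(ep_losses, weights=wts)))
        log.train_dice.append(float(np.average(ep_dices, weights=wts)))
        va_loss, va_dice = evaluate(net, x_va, y_va, config.batch_size)
        log.val_loss.append(va_loss)
        log.val_dice.append(va_dice)
        log.lr.append(lr)
        if va_dice > best_dice:  # strict: ties keep the earlier epoch
            best_dice = va_dice
            best_state = net.state_dict()
            log.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.2e}  "
                  f"train loss {log.train_loss[-1]:.4f} dice "
                  f"{log.train_dice[-1]:.4f}  val loss {va_loss:.4f} "
                  f"dice {va_dice:.4f}")
        if callback is not None:
            callback(epoch, log)

    best_net = UNet(net.config, dtype=net.dtype)
    best_net.load_state_dict(best_state)
    return best_net, log
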