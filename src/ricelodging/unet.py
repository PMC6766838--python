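"""A UNet encoder-decoder for lodging segmentation.

The architecture is the classic 4-level UNet with two modifications that make
it suit canopy rasters: every convolution is 3x3 with padding 1 followed by
batch normalization and ReLU, so encoder and decoder feature maps line up
exactly and skip tensors are concatenated without cropping; and the head is a
single-channel 1x1 convolution whose sigmoid gives a per-pixel lodging
probability.

With the default base width of 64 the encoder runs 3 -> 64 -> 128 -> 256 ->
512 -> 1024 channels while the spatial extent shrinks by 2x at each of the 4
max-pool stages, so a 320x320 input reaches a 20x20x1024 bottleneck; the
decoder mirrors this with 2x2-stride transposed convolutions back to a
64-channel full-resolution map.  Inputs must therefore have height and width
divisible by 2**levels (= 16).

The network is fully convolutional: the same weights run on any admissible
size, which is what sliding-window inference on large mosaics relies on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, ReLU,
                 conv_fans, sigmoid, xavier_uniform)

__all__ = ["NetConfig", "UNet", "ShapeError", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT = "ricelodging-unet-v1"


class ShapeError(ValueError):
    """Input spatial size incompatible with the pooling depth."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    in_channels: 3 for RGB/RGN imagery or index triples, 6 for full index
    stacks.  base_channels: width of the first encoder block; widths double at
    each of `levels` pooling stages.  out_channels: 1 (lodging probability).
    """

    in_channels: int = 3
    base_channels: int = 64
    levels: int = 4
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.base_channels < 1 or self.levels < 1 or self.out_channels < 1:
            raise ValueError("base_channels, levels, out_channels must be >= 1")

    @property
    def divisor(self) -> int:
        return 2 ** self.levels

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** self.levels

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** i for i in range(self.levels + 1))


class _DoubleConv:
    """(Conv 3x3 pad 1 -> BN -> ReLU) x 2."""

    def __init__(self, cin: int, cout: int, dtype=np.float32) -> None:
        self.layers = [
            Conv2d(cin, cout, 3, dtype=dtype), BatchNorm2d(cout, dtype=dtype), ReLU(),
            Conv2d(cout, cout, 3, dtype=dtype), BatchNorm2d(cout, dtype=dtype), ReLU(),
        ]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class UNet:
    """The segmentation network; weights are Xavier-initialized under a seed."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0,
                 dtype=np.float32) -> None:
        self.config = config or NetConfig()
        self.dtype = dtype
        cfg = self.config
        b, L = cfg.base_channels, cfg.levels

        self.inc = _DoubleConv(cfg.in_channels, b, dtype)
        # one pool per stage: each caches its own argmax for backward
        self.pools = [MaxPool2d() for _ in range(L)]
        self.downs = [_DoubleConv(b * 2 ** i, b * 2 ** (i + 1), dtype)
                      for i in range(L)]
        self.upconvs = [ConvTranspose2d(b * 2 ** (i + 1), b * 2 ** i, dtype)
                        for i in reversed(range(L))]
        self.updouble = [_DoubleConv(b * 2 ** (i + 1), b * 2 ** i, dtype)
                         for i in reversed(range(L))]
        self.outc = Conv2d(b, cfg.out_channels, kernel=1, pad=0, dtype=dtype)
        self._init_weights(seed)

    # -- parameter registry ------------------------------------------------

    def modules(self):
        """Yield (path, layer) for every parametrized layer, fixed order."""
        yield from ((f"inc.{i}", l) for i, l in enumerate(self.inc.layers))
        for d, blk in enumerate(self.downs):
            yield from ((f"down{d}.{i}", l) for i, l in enumerate(blk.layers))
        for u in range(len(self.upconvs)):
            yield f"up{u}.tconv", self.upconvs[u]
            yield from ((f"up{u}.{i}", l)
                        for i, l in enumerate(self.updouble[u].layers))
        yield "outc", self.outc

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for path, layer in self.modules():
            for key, val in layer.params.items():
                out[f"{path}.{key}"] = val
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for path, layer in self.modules():
            for key, val in layer.grads.items():
                out[f"{path}.{key}"] = val
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for path, layer in self.modules():
            for key, val in layer.params.items():
                out[f"{path}.{key}"] = val.copy()
            for key, val in layer.buffers.items():
                out[f"{path}.{key}"] = val.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for path, layer in self.modules():
            for key in layer.params:
                src = state[f"{path}.{key}"]
                if src.shape != layer.params[key].shape:
                    raise ValueError(f"shape mismatch for {path}.{key}")
                layer.params[key] = src.copy()
            for key in layer.buffers:
                layer.buffers[key] = state[f"{path}.{key}"].copy()

    def _init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for _, layer in self.modules():
            if isinstance(layer, (Conv2d, ConvTranspose2d)):
                w = layer.params["weight"]
                fin, fout = conv_fans(w.shape,
                                      transposed=isinstance(layer, ConvTranspose2d))
                layer.params["weight"] = xavier_uniform(w.shape, rng, fin, fout,
                                                        self.dtype)
                layer.params["bias"][:] = 0

    # -- forward / backward ------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ShapeError(f"expected NCHW batch, got shape {x.shape}")
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(
                f"network expects {self.config.in_channels} channels, got {c}")
        d = self.config.divisor
        if h % d or w % d:
            raise ShapeError(
                f"input {h}x{w} not divisible by 2^levels = {d}; "
                f"pad to a multiple of {d}")

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       features: dict | None = None,
                       drop_skips: frozenset | None = None) -> np.ndarray:
        """Raw single-channel logits.

        ``features`` collects named feature maps ("bottleneck",
        "decoder_last").  ``drop_skips`` is an ablation diagnostic: skip
        tensors at the given encoder levels (0 = shallowest) are zeroed
        before concatenation.
        """
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        h = self.inc.forward(x, train)
        for pool, blk in zip(self.pools, self.downs):
            skips.append(h)
            h = blk.forward(pool.forward(h, train), train)
        if features is not None:
            features["bottleneck"] = h
        self._skip_channels = [s.shape[1] for s in skips]
        for up, blk in zip(self.upconvs, self.updouble):
            skip = skips.pop()
            if drop_skips and len(skips) in drop_skips:
                skip = np.zeros_like(skip)
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        if features is not None:
            features["decoder_last"] = h
        return self.outc.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel lodging probabilities in (0, 1), shape (N, 1, H, W)."""
        return sigmoid(self.forward_logits(x, train=train))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate a logit gradient; fills every layer's ``grads``."""
        g = self.outc.backward(dlogits)
        # walk the decoder shallowest-first (reverse of application order),
        # collecting each concatenated skip's gradient share
        skip_grads = []
        for up, blk, ch in zip(reversed(self.upconvs), reversed(self.updouble),
                               self._skip_channels):
            g = blk.backward(g)
            skip_grads.append(g[:, :ch].copy())
            g = up.backward(np.ascontiguousarray(g[:, ch:]))
        # encoder backward deepest-first; each stage's input fed both the pool
        # path and a skip, so the two gradients add
        for pool, blk in zip(reversed(self.pools), reversed(self.downs)):
            g = blk.backward(g)
            g = pool.backward(g)
            g = g + skip_grads.pop()
        return self.inc.backward(g)

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.named_params().values())


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, net: UNet, epoch: int | None = None,
                    extra: dict | None = None) -> None:
    """Save weights + config (+ optional metadata) to a self-describing .npz."""
    header = {
        "format": CHECKPOINT_FORMAT,
        "config": asdict(net.config),
        "epoch": epoch,
        "extra": extra or {},
    }
    arrays = {f"state/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[UNet, dict]:
    """Rebuild a UNet from a checkpoint; returns (net, header)."""
    with np.load(Path(path), allow_pickle=False) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"{path}: not a recognized checkpoint")
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    net = UNet(NetConfig(**header["config"]))
    net.load_state_dict(state)
    return net, header
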