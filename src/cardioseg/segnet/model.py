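"""Patch-based 3D U-Net with five sigmoid output channels.

Encoder-decoder with skip connections; each block is (conv3 -> ReLU -> group
norm) twice, downsampling by 2× max pooling and upsampling by nearest
neighbor.  The final 1³ convolution maps to one binary channel per main
structure, squashed by a sigmoid — segmentation is five binary tasks, not
one multiclass task, and channels are combined by a fixed priority at
prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from ..core import ImagingError, LABEL_PRIORITY
from .nn import Conv3d, GroupNorm, MaxPool2, ReLU, Sigmoid, Upsample2


@dataclass
class PatchSpec:
    """Patch size and stride, (dz, dy, dx) voxels."""

    size: tuple[int, int, int] = (64, 100, 100)
    stride: tuple[int, int, int] = (32, 64, 64)

    def __post_init__(self):
        if any(s <= 0 or s > p for s, p in zip(self.stride, self.size)):
            raise ImagingError("need 0 < stride <= patch size componentwise")


@dataclass
class TrainConfig:
    """Optimizer, schedule and architecture hyperparameters.

    Defaults are the full-scale profile (feature scale 64, 16 norm groups,
    Adam at 1e-4 with 1e-4 weight decay, multi-step LR decay by gamma=0.1,
    100 epochs, batch size 1).  ``desk_profile`` returns a configuration
    small enough to train in minutes on one CPU.
    """

    base_features: int = 64
    groups: int = 16
    levels: int = 4
    lr: float = 1e-4
    weight_decay: float = 1e-4
    gamma: float = 0.1
    milestones: tuple[int, ...] = (50, 75)
    epochs: int = 100
    batch_size: int = 1
    dice_eps: float = 1.0
    seed: int = 0
    clip_window: tuple[float, float] = (-1000.0, 800.0)
    max_iterations: int | None = None
    n_channels: int = 5

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ImagingError("gamma must be in (0, 1)")
        if self.dice_eps <= 0:
            raise ImagingError("dice_eps must be > 0")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ImagingError("milestones must be strictly increasing")


def desk_profile(**overrides) -> TrainConfig:
    """A CPU-sized training profile (small features, few epochs, high LR)."""
    cfg = dict(
        base_features=8,
        groups=4,
        levels=3,
        lr=1e-2,
        epochs=25,
        milestones=(15, 20),
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


class _Block:
    """(conv -> ReLU -> group norm) x2."""

    def __init__(self, cin, cout, groups, rng):
        self.layers = [
            Conv3d(cin, cout, 3, rng),
            ReLU(),
            GroupNorm(cout, groups),
            Conv3d(cout, cout, 3, rng),
            ReLU(),
            GroupNorm(cout, groups),
        ]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """3D U-Net; input (1, D, H, W), output (n_channels, D, H, W) in (0, 1).

    Spatial dims must be divisible by 2^(levels-1).
    """

    def __init__(self, config: TrainConfig):
        if config.base_features % config.groups != 0:
            raise ImagingError(
                f"base features {config.base_features} not divisible by "
                f"{config.groups} norm groups"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.levels
        feats = [config.base_features * 2**i for i in range(L)]
        self.enc = [
            _Block(1 if i == 0 else feats[i - 1], feats[i], config.groups, rng)
            for i in range(L)
        ]
        self.pools = [MaxPool2() for _ in range(L - 1)]
        self.ups = [Upsample2() for _ in range(L - 1)]
        self.dec = [
            _Block(feats[i + 1] + feats[i], feats[i], config.groups, rng)
            for i in reversed(range(L - 1))
        ]
        self.head = Conv3d(feats[0], config.n_channels, 1, rng)
        self.sigmoid = Sigmoid()

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        for blk in self.enc + self.dec:
            yield from blk.layers
        yield self.head

    def parameters(self):
        for i, layer in enumerate(self._all_layers()):
            for name, p in layer.params.items():
                yield f"{i}.{name}", layer, name

    def parameter_count(self) -> int:
        return sum(layer.params[name].size for _, layer, name in self.parameters())

    def zero_grad(self):
        for layer in self._all_layers():
            layer.grads = {}

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        div = 2 ** (self.config.levels - 1)
        if any(s % div for s in x.shape[1:]):
            raise ImagingError(
                f"patch dims {x.shape[1:]} must be divisible by {div}"
            )
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h)
        for j, blk in enumerate(self.dec):
            up = self.ups[j].forward(h)
            skip = skips[-(j + 1)]
            h = blk.forward(np.concatenate([up, skip], axis=0))
        self._skip_channels = [s.shape[0] for s in skips]
        logits = self.head.forward(h)
        return self.sigmoid.forward(logits)

    def backward(self, dy: np.ndarray):
        dy = self.sigmoid.backward(dy)
        dy = self.head.backward(dy)
        dskips = [None] * len(self.enc[:-1])
        for j in reversed(range(len(self.dec))):
            dcat = self.dec[j].backward(dy)
            n_up = dcat.shape[0] - self._skip_channels[-(j + 1)]
            dup, dskip = dcat[:n_up], dcat[n_up:]
            dskips[len(self.dec) - 1 - j] = dskip
            dy = self.ups[j].backward(dup)
        for i in reversed(range(len(self.enc))):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)
        return dy

    # -- persistence ---------------------------------------------------------
    def save(self, path):
        path = Path(path)
        arrays = {}
        for key, layer, name in self.parameters():
            arrays[key] = layer.params[name]
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = {k: v for k, v in vars(self.config).items()}
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()
        }
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path) -> "UNet3D":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        for k in ("milestones", "clip_window"):
            if cfg.get(k) is not None:
                cfg[k] = tuple(cfg[k])
        model = cls(TrainConfig(**cfg))
        data = np.load(path.with_suffix(".npz"))
        for key, layer, name in model.parameters():
            layer.params[name] = data[key]
        return model


def conv_parameter_count(cin: int, cout: int, k: int = 3) -> int:
    """Analytic parameter count of one convolution (weights + biases)."""
    return cout * (cin * k**3 + 1)


__all__ = [
    "PatchSpec",
    "TrainConfig",
    "desk_profile",
    "UNet3D",
    "conv_parameter_count",
]
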