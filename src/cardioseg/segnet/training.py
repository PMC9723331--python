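"""Patch extraction, Dice loss, Adam training loop, sliding-window prediction.

Training consumes bounding-box-cropped volumes with (computer-generated)
labels, splits them into overlapping patches, and optimizes the mean
per-channel Dice loss with Adam under a multi-step learning-rate schedule.
Prediction slides the patch grid over the crop, averages overlapping channel
probabilities, thresholds each channel at 0.5, and combines the five binary
masks by the fixed structure priority (LV, LA, RV, RA, LVM) — a voxel
positive in several channels takes the earliest structure in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..bbox import BoundingBox, crop, uncrop
from ..core import (
    ImagingError,
    LABEL_PRIORITY,
    LabelMap,
    STRUCTURE_CODES,
    Volume,
)
from .model import PatchSpec, TrainConfig, UNet3D


def axis_starts(length: int, patch: int, stride: int) -> list[int]:
    """Patch start offsets 0, s, 2s, ... with a final start clamped so the
    last patch touches the far edge."""
    if length <= patch:
        return [0]
    starts = list(range(0, length - patch + 1, stride))
    if starts[-1] + patch < length:
        starts.append(length - patch)
    return starts


def _binary_channels(label_data: np.ndarray, code_table) -> np.ndarray:
    return np.stack(
        [(label_data == code_table[s]).astype(np.float64) for s in LABEL_PRIORITY]
    )


def _pad_to(data: np.ndarray, size, fill=0.0) -> np.ndarray:
    pads = [(0, max(0, p - s)) for s, p in zip(data.shape[-3:], size)]
    if data.ndim == 4:
        pads = [(0, 0)] + pads
    if all(p == (0, 0) for p in pads):
        return data
    return np.pad(data, pads, constant_values=fill)


def extract_patches(
    volume: Volume, label: LabelMap, spec: PatchSpec
) -> list[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]]:
    """(image patch, 5-channel binary target, start position) tuples.

    Inputs smaller than the patch are padded with background; every voxel is
    covered by at least one patch.
    """
    img = _pad_to(np.asarray(volume.data, dtype=np.float64), spec.size)
    chans = _pad_to(_binary_channels(label.data, label.code_table), spec.size)
    starts = [
        axis_starts(img.shape[a], spec.size[a], spec.stride[a]) for a in range(3)
    ]
    out = []
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (
                    slice(i, i + spec.size[0]),
                    slice(j, j + spec.size[1]),
                    slice(k, k + spec.size[2]),
                )
                out.append((img[sl], chans[(slice(None),) + sl], (i, j, k)))
    return out


def dice_loss(
    pred: np.ndarray, target: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean per-channel soft Dice loss and its gradient w.r.t. ``pred``.

    Per channel: 1 - (2 Σ p t + eps) / (Σ p + Σ t + eps); empty-vs-empty
    channels contribute loss 0 under this smoothing convention.
    """
    if pred.shape != target.shape:
        raise ImagingError(f"shape mismatch: {pred.shape} vs {target.shape}")
    n_ch = pred.shape[0]
    grad = np.empty_like(pred)
    total = 0.0
    for c in range(n_ch):
        p, t = pred[c], target[c]
        inter = float((p * t).sum())
        denom = float(p.sum() + t.sum()) + eps
        total += 1.0 - (2.0 * inter + eps) / denom
        grad[c] = -(2.0 * t * denom - (2.0 * inter + eps)) / denom**2
    return total / n_ch, grad / n_ch


def normalize_intensity(data: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (np.clip(data, lo, hi) - lo) / (hi - lo)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, model: UNet3D, lr: float, weight_decay: float):
        self.model = model
        self.lr = lr
        self.wd = weight_decay
        self.t = 0
        self.m = {}
        self.v = {}
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for key, layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g + self.wd * layer.params[name]
            m = self.m.get(key, 0.0) * self.b1 + (1 - self.b1) * g
            v = self.v.get(key, 0.0) * self.b2 + (1 - self.b2) * g**2
            self.m[key], self.v[key] = m, v
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Multi-step schedule: LR drops by gamma at each milestone epoch."""
    drops = sum(1 for m in config.milestones if epoch >= m)
    return config.lr * config.gamma**drops


@dataclass
class EpochLog:
    epoch: int
    mean_loss: float
    lr: float


def train(
    cases: list[tuple[Volume, LabelMap, BoundingBox]],
    config: TrainConfig,
    patch_spec: PatchSpec,
    checkpoint_path=None,
) -> tuple[UNet3D, list[EpochLog]]:
    """Train a U-Net on bounding-box crops of the given cases.

    Deterministic given ``config.seed`` (patch shuffling and weight
    initialisation both derive from it).  Returns the model and the
    per-epoch loss/LR history; ``config.max_iterations`` caps the total
    number of optimizer steps when set.
    """
    if not cases:
        raise ImagingError("no training cases")
    patches = []
    for vol, lab, box in cases:
        v, l = crop(vol, box), crop(lab, box)
        for img, tgt, _pos in extract_patches(v, l, patch_spec):
            patches.append((normalize_intensity(img, config.clip_window), tgt))

    model = UNet3D(config)
    opt = Adam(model, config.lr, config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    history: list[EpochLog] = []
    it = 0
    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(config, epoch)
        order = rng.permutation(len(patches))
        losses = []
        for pi in order:
            img, tgt = patches[pi]
            pred = model.forward(img[None])
            loss, dpred = dice_loss(pred, tgt, config.dice_eps)
            model.zero_grad()
            model.backward(dpred)
            opt.step()
            losses.append(loss)
            it += 1
            if config.max_iterations is not None and it >= config.max_iterations:
                break
        history.append(EpochLog(epoch, float(np.mean(losses)), opt.lr))
        if config.max_iterations is not None and it >= config.max_iterations:
            break
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return model, history


def predict(
    model: UNet3D,
    volume: Volume,
    box: BoundingBox,
    patch_spec: PatchSpec,
    priority: tuple[str, ...] = LABEL_PRIORITY,
    threshold: float = 0.5,
) -> LabelMap:
    """Sliding-window prediction embedded back into the full grid.

    Overlapping patch probabilities are averaged per voxel per channel before
    thresholding.
    """
    if sorted(priority) != sorted(LABEL_PRIORITY):
        raise ImagingError("priority must be a permutation of the five structures")
    config = model.config
    vcrop = crop(volume, box)
    img = _pad_to(
        normalize_intensity(np.asarray(vcrop.data, dtype=np.float64), config.clip_window),
        patch_spec.size,
    )
    acc = np.zeros((config.n_channels, *img.shape))
    cnt = np.zeros(img.shape)
    starts = [
        axis_starts(img.shape[a], patch_spec.size[a], patch_spec.stride[a])
        for a in range(3)
    ]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (
                    slice(i, i + patch_spec.size[0]),
                    slice(j, j + patch_spec.size[1]),
                    slice(k, k + patch_spec.size[2]),
                )
                acc[(slice(None),) + sl] += model.forward(img[sl][None])
                cnt[sl] += 1
    probs = acc / cnt[None]
    crop_shape = vcrop.shape
    probs = probs[:, : crop_shape[0], : crop_shape[1], : crop_shape[2]]
    out = np.zeros(crop_shape, dtype=np.int16)
    for s in priority:  # earliest structure in priority wins
        ch = LABEL_PRIORITY.index(s)
        m = (probs[ch] > threshold) & (out == 0)
        out[m] = STRUCTURE_CODES[s]
    lab = LabelMap(out, vcrop.spacing, vcrop.origin)
    return uncrop(lab, box, volume.shape)


__all__ = [
    "axis_starts",
    "extract_patches",
    "dice_loss",
    "normalize_intensity",
    "Adam",
    "lr_at_epoch",
    "EpochLog",
    "train",
    "predict",
]
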