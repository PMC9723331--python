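"""Minimal 3D neural-network layers with explicit backpropagation.

Tensors are numpy arrays of shape (C, D, H, W) — batch size is fixed at 1,
matching the training regime (one patch per optimizer step).  Each layer
caches what its backward pass needs; ``backward`` consumes dL/d(output) and
returns dL/d(input), accumulating parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv3d(Layer):
    """k³ convolution, stride 1, 'same' padding for k=3 / none for k=1."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None):
        super().__init__()
        assert k in (1, 3)
        self.cin, self.cout, self.k = cin, cout, k
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        # He initialisation, appropriate before ReLU
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in))
        self.params["b"] = np.zeros(cout)

    def forward(self, x):
        self.x_shape = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        else:
            xp = x
        if k == 1:
            cols = x.reshape(self.cin, -1)
        else:
            win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
            # (cin, D, H, W, k, k, k) -> (cin*k^3, N)
            cols = win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(self.cin * k**3, -1)
        self.cols = np.ascontiguousarray(cols)
        y = self.params["W"] @ self.cols + self.params["b"][:, None]
        return y.reshape(self.cout, *x.shape[1:])

    def backward(self, dy):
        k = self.k
        dyf = dy.reshape(self.cout, -1)
        self.grads["W"] = self.grads.get("W", 0) + dyf @ self.cols.T
        self.grads["b"] = self.grads.get("b", 0) + dyf.sum(axis=1)
        dcols = self.params["W"].T @ dyf  # (cin*k^3, N)
        _, D, H, W = self.x_shape
        if k == 1:
            return dcols.reshape(self.x_shape)
        dcols = dcols.reshape(self.cin, k, k, k, D, H, W)
        dxp = np.zeros((self.cin, D + 2, H + 2, W + 2))
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, a : a + D, b : b + H, c : c + W] += dcols[:, a, b, c]
        return dxp[:, 1 : 1 + D, 1 : 1 + H, 1 : 1 + W]


class GroupNorm(Layer):
    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups != 0:
            raise ValueError(
                f"channels ({channels}) not divisible by norm groups ({groups})"
            )
        self.c, self.g, self.eps = channels, groups, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)

    def forward(self, x):
        self.shape = x.shape
        xg = x.reshape(self.g, -1)
        self.mu = xg.mean(axis=1, keepdims=True)
        self.var = xg.var(axis=1, keepdims=True)
        self.xhat = ((xg - self.mu) / np.sqrt(self.var + self.eps)).reshape(x.shape)
        return self.xhat * self.params["gamma"][:, None, None, None] + self.params[
            "beta"
        ][:, None, None, None]

    def backward(self, dy):
        g = self.g
        self.grads["gamma"] = self.grads.get("gamma", 0) + (dy * self.xhat).sum(
            axis=(1, 2, 3)
        )
        self.grads["beta"] = self.grads.get("beta", 0) + dy.sum(axis=(1, 2, 3))
        dxhat = (dy * self.params["gamma"][:, None, None, None]).reshape(g, -1)
        xhat = self.xhat.reshape(g, -1)
        m = dxhat.shape[1]
        inv_std = 1.0 / np.sqrt(self.var + self.eps)
        dx = inv_std * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
        )
        return dx.reshape(self.shape)


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class Sigmoid(Layer):
    def forward(self, x):
        self.y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self.y

    def backward(self, dy):
        return dy * self.y * (1.0 - self.y)


class MaxPool2(Layer):
    """2× max pooling; spatial dims must be even."""

    def forward(self, x):
        c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "odd spatial dims"
        self.x_shape = x.shape
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            c, d // 2, h // 2, w // 2, 8
        )
        self.arg = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self.arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        c, d, h, w = self.x_shape
        dblocks = np.zeros((c, d // 2, h // 2, w // 2, 8))
        np.put_along_axis(dblocks, self.arg[..., None], dy[..., None], axis=-1)
        dblocks = dblocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        return dblocks.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)


class Upsample2(Layer):
    """2× nearest-neighbor upsampling."""

    def forward(self, x):
        self.x_shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        c, d, h, w = self.x_shape
        return (
            dy.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))
        )


__all__ = ["Layer", "Conv3d", "GroupNorm", "ReLU", "Sigmoid", "MaxPool2", "Upsample2"]
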