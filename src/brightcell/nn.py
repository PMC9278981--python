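"""Minimal numpy implementation of the small convolutional classifier.

The network mirrors the shallow architecture used throughout the package:
two or three valid-mode 5x5 convolutional layers, each followed by ReLU and
2x2 max pooling, then a single fully connected layer emitting one logit per
class.  Training uses softmax cross-entropy with the Adam optimizer.  All
state is plain numpy, so runs are bit-reproducible given a seed and a model
serializes to a single ``.npz`` file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "conv_stack_output_side"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, oh*ow, C*k*k)
    n, c, h, w = x.shape
    sw = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, oh, ow, k, k)
    oh, ow = h - k + 1, w - k + 1
    return np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(n, oh * ow, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh, ow = h - k + 1, w - k + 1
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    d6 = dcols.reshape(n, oh, ow, c, k, k)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh, j : j + ow] += d6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        n, _, h, w = x.shape
        oh, ow = h - self.k + 1, w - self.k + 1
        out = self._cols @ self.w.T + self.b
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c_out, oh, ow = dout.shape
        d2 = dout.transpose(0, 2, 3, 1).reshape(n, oh * ow, c_out)
        self.dw = np.einsum("npo,npf->of", d2, self._cols)
        self.db = d2.sum(axis=(0, 1))
        dcols = d2 @ self.w
        return _col2im(dcols, self._x_shape, self.k)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    """2x2 max pooling with floor division; skipped upstream if side < 2."""

    def forward(self, x):
        n, c, h, w = x.shape
        hc, wc = (h // 2) * 2, (w // 2) * 2
        self._in_shape = x.shape
        v = x[:, :, :hc, :wc].reshape(n, c, hc // 2, 2, wc // 2, 2)
        v4 = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hc // 2, wc // 2, 4)
        self._idx = v4.argmax(axis=-1)
        return np.take_along_axis(v4, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, oh, ow = dout.shape
        dv4 = np.zeros((n, c, oh, ow, 4), dtype=dout.dtype)
        np.put_along_axis(dv4, self._idx[..., None], dout[..., None], axis=-1)
        dv = dv4.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : oh * 2, : ow * 2] = dv.reshape(n, c, oh * 2, ow * 2)
        return dx


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.w

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


def conv_stack_output_side(input_side: int, n_conv_layers: int, kernel: int = 5) -> int:
    """Spatial side after the conv/pool stack; raises if the stack collapses.

    Pooling is applied only when the post-convolution side is at least 2,
    which is what lets a 15-px input drive a two-layer stack.
    """
    side = input_side
    for _ in range(n_conv_layers):
        side = side - kernel + 1
        if side < 1:
            raise ValueError(
                f"input side {input_side} incompatible with {n_conv_layers} conv layers"
            )
        if side >= 2:
            side //= 2
    return side


@dataclass
class SmallCNN:
    """Shallow conv net for square single-channel tiles.

    Parameters
    ----------
    input_side : tile side in pixels (36 default; 15 for the halved-size study).
    n_conv_layers : 2 or 3 convolutional layers.
    channels : filters per conv layer; trailing entries ignored if fewer layers.
    n_classes : size of the output score vector.
    seed : initialization / shuffling seed.
    """

    input_side: int = 36
    n_conv_layers: int = 3
    channels: tuple = (16, 32, 64)
    kernel_size: int = 5
    n_classes: int = 2
    seed: int = 0
    input_mode: str = "uint8"  # "uint8": /255; "standardize": per-tile z-score; "raw"
    layers: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.n_conv_layers not in (2, 3):
            raise ValueError("n_conv_layers must be 2 or 3")
        rng = np.random.default_rng(self.seed)
        side = self.input_side
        c_in = 1
        self.layers = []
        for i in range(self.n_conv_layers):
            c_out = self.channels[i]
            self.layers.append(_Conv(c_in, c_out, self.kernel_size, rng))
            self.layers.append(_ReLU())
            side = side - self.kernel_size + 1
            if side < 1:
                raise ValueError("conv stack collapses below 1 px; reduce layers or kernel")
            if side >= 2:
                self.layers.append(_MaxPool2())
                side //= 2
            c_in = c_out
        self._flat_dim = c_in * side * side
        self.layers.append(_Linear(self._flat_dim, self.n_classes, rng))

    # -- forward / backward -------------------------------------------------
    def _prepare(self, tiles: np.ndarray) -> np.ndarray:
        x = np.asarray(tiles, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if self.input_mode == "uint8":
            x = x / 255.0
        elif self.input_mode == "standardize":
            mu = x.mean(axis=(1, 2, 3), keepdims=True)
            sd = x.std(axis=(1, 2, 3), keepdims=True)
            x = (x - mu) / np.maximum(sd, 1e-6)
        elif self.input_mode != "raw":
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            if isinstance(lay, _Linear):
                x = x.reshape(x.shape[0], -1)
            x = lay.forward(x)
        return x

    def predict_scores(self, tiles: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Softmax class-score vectors, one 2-vector (or n_classes) per tile."""
        x = self._prepare(tiles)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out) if out else np.zeros((0, self.n_classes))

    def fit(
        self,
        tiles: np.ndarray,
        labels: np.ndarray,
        epochs: int = 35,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
    ) -> None:
        x = self._prepare(tiles)
        y = np.asarray(labels, dtype=np.int64)
        if x.shape[0] != y.shape[0]:
            raise ValueError("tiles and labels length mismatch")
        rng = np.random.default_rng(self.seed + 1)
        params = []
        for lay in self.layers:
            if hasattr(lay, "params"):
                params.extend(p for _, p in lay.params())
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(x)
        for _ in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self.forward(xb)
                logits = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                probs = e / e.sum(axis=1, keepdims=True)
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                # backward
                grad = dlogits
                for lay in reversed(self.layers):
                    grad = lay.backward(grad)
                    if isinstance(lay, _Linear):
                        grad = grad.reshape(self._last_conv_shape(xb, lay))
                grads = []
                for lay in self.layers:
                    if hasattr(lay, "grads"):
                        grads.extend(lay.grads())
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)

    def _last_conv_shape(self, xb, linear_layer):
        # shape feeding the flatten before the linear layer
        n = xb.shape[0]
        side = self.input_side
        c = 1
        for i in range(self.n_conv_layers):
            c = self.channels[i]
            side = side - self.kernel_size + 1
            if side >= 2:
                side //= 2
        return (n, c, side, side)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        meta = dict(
            input_side=self.input_side,
            n_conv_layers=self.n_conv_layers,
            channels=list(self.channels),
            kernel_size=self.kernel_size,
            n_classes=self.n_classes,
            seed=self.seed,
            input_mode=self.input_mode,
        )
        arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        i = 0
        for lay in self.layers:
            if hasattr(lay, "params"):
                for name, p in lay.params():
                    arrays[f"p{i}_{name}"] = p
                i += 1
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SmallCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            meta["channels"] = tuple(meta["channels"])
            model = cls(**meta)
            i = 0
            for lay in model.layers:
                if hasattr(lay, "params"):
                    for name, _ in lay.params():
                        setattr(lay, name, data[f"p{i}_{name}"].copy())
                    i += 1
        return model
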