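"""Numpy implementation of the VGG-style GAP-head classifier.

Convolutions run as im2col matrix products; every layer implements an exact
backward pass, verified against finite differences in the test suite. The
backward pass records gradients with respect to the post-activation output
of every convolution, which is what Grad-CAM consumes.
"""

from __future__ import annotations

import numpy as np

from .arch import ArchitectureSpec

__all__ = ["ConvNet", "build_model"]


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, shape).astype(np.float64)


class _Conv:
    """3x3 (or k x k) stride-1 same-padding convolution + ReLU."""

    def __init__(self, rng, c_in, c_out, k, name):
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.name = name
        self.w = _he_uniform(rng, k * k * c_in, (c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x):
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (b, c, h, w, k, k) -> (b, h*w, c*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * self.k * self.k)

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = self._im2col(x)
        b, c, h, w = x.shape
        z = self.cols @ self.w.T + self.b
        z = z.transpose(0, 2, 1).reshape(b, self.c_out, h, w)
        self.relu_mask = z > 0
        self.out = np.where(self.relu_mask, z, 0.0)
        return self.out

    def backward(self, dout):
        b, c, h, w = self.x_shape
        dz = np.where(self.relu_mask, dout, 0.0)
        self.grad_out = dout  # gradient w.r.t. post-ReLU activation (Grad-CAM)
        dz2 = dz.reshape(b, self.c_out, h * w).transpose(0, 2, 1)  # (b, hw, cout)
        self.dw += np.einsum("bpo,bpi->oi", dz2, self.cols)
        self.db += dz2.sum(axis=(0, 1))
        dcols = dz2 @ self.w  # (b, hw, c*k*k)
        # col2im scatter-add
        p = self.k // 2
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        dcols = dcols.reshape(b, h, w, c, self.k, self.k)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class _MaxPool:
    """2x2 stride-2 max pool; gradient split evenly among tied maxima."""

    def forward(self, x):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h}, {w}) not divisible by 2")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        m = xr.max(axis=(3, 5), keepdims=True)
        mask = xr == m
        self.mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self.in_shape = x.shape
        return m.reshape(b, c, h // 2, w // 2)

    def backward(self, dout):
        b, c, h, w = self.in_shape
        d = dout.reshape(b, c, h // 2, 1, w // 2, 1) * self.mask
        return d.reshape(b, c, h, w)


class ConvNet:
    """Forward map from (batch, H, W, 3) images to tumor probabilities."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers = []
        self.conv_names = []
        c_in = spec.in_channels
        for bi, (n_convs, c_out) in enumerate(spec.blocks):
            for ci in range(n_convs):
                name = f"block{bi + 1}_conv{ci + 1}"
                self.layers.append(_Conv(rng, c_in, c_out, spec.kernel, name))
                self.conv_names.append(name)
                c_in = c_out
            self.layers.append(_MaxPool())
        self.fc_w = _he_uniform(rng, spec.last_channels, (spec.head_width, spec.last_channels))
        self.fc_b = np.zeros(spec.head_width)
        self.out_w = _he_uniform(rng, spec.head_width, (1, spec.head_width))
        self.out_b = np.zeros(1)
        self._zero_head_grads()

    def _zero_head_grads(self):
        self.d_fc_w = np.zeros_like(self.fc_w)
        self.d_fc_b = np.zeros_like(self.fc_b)
        self.d_out_w = np.zeros_like(self.out_w)
        self.d_out_b = np.zeros_like(self.out_b)

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, _Conv):
                out.extend(layer.params)
        out.extend([self.fc_w, self.fc_b, self.out_w, self.out_b])
        return out

    @property
    def grads(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, _Conv):
                out.extend(layer.grads)
        out.extend([self.d_fc_w, self.d_fc_b, self.d_out_w, self.d_out_b])
        return out

    def zero_grads(self):
        for layer in self.layers:
            if isinstance(layer, _Conv):
                layer.dw[:] = 0.0
                layer.db[:] = 0.0
        self._zero_head_grads()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_state(self):
        return [p.copy() for p in self.params]

    def set_state(self, state):
        for p, s in zip(self.params, state):
            p[:] = s

    # -- forward / backward -------------------------------------------------

    def _to_bchw(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        c = self.spec.in_channels
        if x.shape[1] != c:
            if x.shape[-1] != c:
                raise ValueError(f"expected {c}-channel input, got shape {x.shape}")
            x = x.transpose(0, 3, 1, 2)
        return x

    def forward_logits(self, images: np.ndarray) -> np.ndarray:
        x = self._to_bchw(images)
        h, w = x.shape[2], x.shape[3]
        self.spec.feature_map_size(h, w)  # shape validation
        for layer in self.layers:
            x = layer.forward(x)
        self.gap_in_shape = x.shape
        g = x.mean(axis=(2, 3))  # (b, c)
        self.gap_out = g
        z1 = g @ self.fc_w.T + self.fc_b
        self.fc_mask = z1 > 0
        a1 = np.where(self.fc_mask, z1, 0.0)
        self.fc_out = a1
        return (a1 @ self.out_w.T + self.out_b).ravel()

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        z = self.forward_logits(images)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate gradients of a scalar loss w.r.t. the logits."""
        d = np.asarray(dlogits, dtype=np.float64).reshape(-1, 1)
        self.d_out_w += d.T @ self.fc_out
        self.d_out_b += d.sum(axis=0)
        da1 = d @ self.out_w
        dz1 = np.where(self.fc_mask, da1, 0.0)
        self.d_fc_w += dz1.T @ self.gap_out
        self.d_fc_b += dz1.sum(axis=0)
        dg = dz1 @ self.fc_w
        b, c, hh, ww = self.gap_in_shape
        dx = np.broadcast_to(dg[:, :, None, None], (b, c, hh, ww)) / (hh * ww)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    # -- Grad-CAM hooks -----------------------------------------------------

    def conv_layer(self, name: str) -> _Conv:
        for layer in self.layers:
            if isinstance(layer, _Conv) and layer.name == name:
                return layer
        raise KeyError(f"unknown conv layer {name!r}")

    def last_conv_of_last_blocks(self, n: int = 2) -> list[str]:
        names = []
        idx = 0
        for n_convs, _ in self.spec.blocks:
            idx += n_convs
            names.append(self.conv_names[idx - 1])
        return names[-n:]


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ConvNet:
    """Instantiate a randomly initialized (He-uniform) network."""
    return ConvNet(spec, seed=seed)
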