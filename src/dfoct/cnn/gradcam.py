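"""Grad-CAM attention maps.

Gradients of the chosen class logit are backpropagated to convolutional
activations; the spatial mean of each channel's gradient weights that
channel's activation map, and the rectified weighted sum is the attention
map. The default fuses the last convolutional layer of the last two blocks,
upsampling the coarser map 2x (nearest neighbor) before summation, which
adds finer spatial detail from the higher-resolution block. For the single
sigmoid output, the negative (healthy) class uses the complementary logit
-z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net import ConvNet

__all__ = ["AttentionMap", "gradcam"]


@dataclass
class AttentionMap:
    map: np.ndarray
    source_layers: tuple[str, ...]
    target: str

    def upsampled(self, shape: tuple[int, int]) -> np.ndarray:
        """Nearest-neighbor upsampling to an output shape (display overlay)."""
        h, w = self.map.shape
        ys = (np.arange(shape[0]) * h // shape[0]).clip(0, h - 1)
        xs = (np.arange(shape[1]) * w // shape[1]).clip(0, w - 1)
        return self.map[np.ix_(ys, xs)]


def _layer_cam(layer) -> np.ndarray:
    a = layer.out[0]          # (c, h, w) post-ReLU activation
    g = layer.grad_out[0]     # gradient of target logit w.r.t. activation
    weights = g.mean(axis=(1, 2))
    cam = np.tensordot(weights, a, axes=(0, 0))
    return np.maximum(cam, 0.0)


def _upsample2(cam: np.ndarray) -> np.ndarray:
    return np.kron(cam, np.ones((2, 2)))


def gradcam(
    model: ConvNet,
    image: np.ndarray,
    target: str = "positive",
    layers: tuple[str, ...] | None = None,
) -> AttentionMap:
    """Attention map for one image.

    ``target='positive'`` explains the tumor logit, ``'negative'`` the
    complementary (healthy) logit. ``layers`` defaults to the last conv layer
    of the last two blocks; maps are rectified per layer, coarser maps
    upsampled 2x per block gap, summed, and rectified.
    """
    if target not in ("positive", "negative"):
        raise ValueError("target must be 'positive' or 'negative'")
    if layers is None:
        layers = tuple(model.last_conv_of_last_blocks(2))
    convs = [model.conv_layer(name) for name in layers]  # raises on unknown
    model.zero_grads()
    model.forward_logits(image[None] if image.ndim == 3 else image)
    sign = 1.0 if target == "positive" else -1.0
    model.backward(np.array([sign]))
    cams = [_layer_cam(c) for c in convs]
    # fuse at the finest participating resolution
    target_hw = max((c.shape for c in cams), key=lambda s: s[0])
    fused = np.zeros(target_hw)
    for cam in cams:
        while cam.shape[0] < target_hw[0]:
            cam = _upsample2(cam)
        fused += cam
    fused = np.maximum(fused, 0.0)
    return AttentionMap(map=fused, source_layers=tuple(layers), target=target)
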