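"""Dataset augmentation: contrast look-up tables and flips.

The default configuration emits, for every input image, three contrast
variants (the untouched original plus two percentile stretches) each in
unflipped and horizontally flipped orientation — six label-preserving
variants replacing the original. Vertical flips are available through
``flip_mode``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LUTS", "DEFAULT_LUTS", "apply_lut", "augment_dataset"]

#: name -> (low percentile, high percentile); None = strict no-op
LUTS: dict = {
    "identity": None,
    "stretch_0_100": (0.0, 100.0),
    "stretch_2_98": (2.0, 98.0),
    "stretch_5_95": (5.0, 95.0),
}

DEFAULT_LUTS = ("identity", "stretch_2_98", "stretch_5_95")


def apply_lut(image: np.ndarray, name: str) -> np.ndarray:
    """Percentile contrast stretch mapped to [0, 1]; 'identity' is a no-op."""
    if name not in LUTS:
        raise ValueError(f"unknown LUT {name!r}; known: {sorted(LUTS)}")
    spec = LUTS[name]
    if spec is None:
        return np.asarray(image).copy()
    lo_p, hi_p = spec
    img = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(img, [lo_p, hi_p])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def _flips(flip_mode: str):
    if flip_mode == "none":
        return [lambda x: x]
    if flip_mode == "horizontal":
        return [lambda x: x, lambda x: x[:, ::-1].copy()]
    if flip_mode == "vertical":
        return [lambda x: x, lambda x: x[::-1].copy()]
    if flip_mode == "both":
        return [lambda x: x, lambda x: x[:, ::-1].copy(), lambda x: x[::-1].copy()]
    raise ValueError(f"unknown flip_mode {flip_mode!r}")


def augment_dataset(
    images: list[np.ndarray],
    labels: list,
    lut_specs: tuple[str, ...] = DEFAULT_LUTS,
    flip_mode: str = "horizontal",
) -> tuple[list[np.ndarray], list]:
    """Expand (images, labels) by LUT x flip combinations, labels preserved.

    Defaults give exactly six variants per input (3 LUTs x {identity,
    horizontal flip}); deterministic (no random transforms).
    """
    if len(images) == 0:
        raise ValueError("at least one image required")
    flips = _flips(flip_mode)
    out_imgs, out_labels = [], []
    for img, lab in zip(images, labels):
        for lut in lut_specs:
            contrasted = apply_lut(img, lut)
            for fl in flips:
                out_imgs.append(fl(contrasted))
                out_labels.append(lab)
    return out_imgs, out_labels
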