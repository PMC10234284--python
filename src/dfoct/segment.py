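"""Random-forest pixel classification of static and dynamic images.

Mirrors the interactive scribble-training workflow common in bio-image
analysis (iLastik-style): each pixel is described by a bank of multiscale
nonlinear filter responses, a random forest is trained on sparsely annotated
pixels only, and the fitted model labels every pixel of new images.

Class sets are fixed per modality:

* dynamic images: ``cells``, ``between_cells``, ``not_cells``;
* static images: ``fibers``, ``around_fibers``, ``cells``, ``fat``.

Interactive scribbling is not reproducible, so scribbles are derived
automatically from phantom ground truth (mask erosion + subsampling); see
:func:`scribbles_from_ground_truth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, structure_tensor, structure_tensor_eigenvalues
from sklearn.ensemble import RandomForestClassifier

from .phantom import GroundTruth

__all__ = [
    "PixelFeatureConfig",
    "PixelClassifierModel",
    "SegmentationMask",
    "DYNAMIC_CLASSES",
    "STATIC_CLASSES",
    "pixel_feature_stack",
    "scribbles_from_ground_truth",
    "train_pixel_classifier",
    "apply_segmentation",
    "mask_from_ground_truth",
]

DYNAMIC_CLASSES = ("cells", "between_cells", "not_cells")
STATIC_CLASSES = ("fibers", "around_fibers", "cells", "fat")

FEATURE_FAMILIES = (
    "gaussian",
    "gradient_magnitude",
    "laplacian",
    "structure_tensor_max_eig",
    "hessian_max_eig",
)


@dataclass(frozen=True)
class PixelFeatureConfig:
    """Multiscale filter bank: every family is evaluated per channel at every
    scale (Gaussian sigma in pixels)."""

    scales: tuple[float, ...] = (0.7, 1.6, 3.5, 7.0)

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("at least one scale is required")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")

    def n_features(self, n_channels: int) -> int:
        return n_channels * len(self.scales) * len(FEATURE_FAMILIES)


@dataclass
class PixelClassifierModel:
    modality: str
    classes: tuple[str, ...]
    forest: RandomForestClassifier
    feature_config: PixelFeatureConfig
    n_channels: int
    training_manifest: dict = field(default_factory=dict)


@dataclass
class SegmentationMask:
    """Dense per-pixel labels; ``class_map`` maps label index to class name."""

    labels: np.ndarray
    class_map: dict
    provenance: str = "model"

    def class_mask(self, name: str) -> np.ndarray:
        idx = [k for k, v in self.class_map.items() if v == name]
        if not idx:
            raise KeyError(f"class {name!r} not in mask")
        return self.labels == idx[0]


def _channel_features(chan: np.ndarray, scales) -> list[np.ndarray]:
    feats = []
    for s in scales:
        smooth = ndi.gaussian_filter(chan, s, mode="reflect")
        feats.append(smooth)
        feats.append(ndi.gaussian_gradient_magnitude(chan, s, mode="reflect"))
        feats.append(ndi.gaussian_laplace(chan, s, mode="reflect"))
        st = structure_tensor(chan, sigma=s, mode="reflect")
        feats.append(structure_tensor_eigenvalues(st)[0])
        hm = hessian_matrix(chan, sigma=s, mode="reflect", use_gaussian_derivatives=False)
        feats.append(hessian_matrix_eigvals(hm)[0])
    return feats


def pixel_feature_stack(image: np.ndarray, config: PixelFeatureConfig | None = None) -> np.ndarray:
    """Per-pixel feature bank, shape (y, x, channels x scales x families).

    Deterministic, translation-equivariant away from borders (reflect
    padding at borders).
    """
    config = config or PixelFeatureConfig()
    image = np.asarray(image, dtype=np.float32)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if image.ndim == 2:
        channels = [image]
    elif image.ndim == 3:
        channels = [image[..., c] for c in range(image.shape[-1])]
    else:
        raise ValueError("image must be 2-D or (y, x, channels)")
    feats: list[np.ndarray] = []
    for chan in channels:
        feats.extend(_channel_features(chan.astype(np.float32), config.scales))
    return np.stack(feats, axis=-1).astype(np.float32)


def scribbles_from_ground_truth(
    gt: GroundTruth,
    modality: str,
    max_per_class: int = 2000,
    erosion_px: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Sparse label mask (0 = unlabeled, i+1 = class i) from phantom truth.

    Each class mask is eroded ``erosion_px`` pixels to keep scribbles away
    from ambiguous boundaries, then at most ``max_per_class`` pixels are
    sampled. Dynamic: cells / a ring around cells (between_cells) / the rest.
    Static: fibers / a ring around fibers / non-fat remainder / fat.
    """
    rng = np.random.default_rng(seed)
    shape = gt.cell_mask.shape
    if modality == "dynamic":
        cells = gt.cell_mask
        ring = ndi.binary_dilation(cells, iterations=6) & ~cells
        rest = ~(cells | ring)
        class_masks = [cells, ring, rest]
    elif modality == "static":
        fibers = gt.fiber_mask
        ring = ndi.binary_dilation(fibers, iterations=4) & ~fibers & ~gt.fat_mask
        fat = gt.fat_mask
        rest = ~(fibers | ring | fat)
        class_masks = [fibers, ring, rest, fat]
    else:
        raise ValueError("modality must be 'static' or 'dynamic'")
    scrib = np.zeros(shape, dtype=np.int32)
    structure = np.ones((3, 3), dtype=bool)
    for i, m in enumerate(class_masks):
        er = ndi.binary_erosion(m, structure=structure, iterations=erosion_px) if erosion_px else m
        if not er.any():
            er = m  # fall back to the raw mask for thin classes
        ys, xs = np.nonzero(er)
        if len(ys) > max_per_class:
            pick = rng.choice(len(ys), max_per_class, replace=False)
            ys, xs = ys[pick], xs[pick]
        scrib[ys, xs] = i + 1
    return scrib


def train_pixel_classifier(
    images: list[np.ndarray],
    scribbles: list[np.ndarray],
    modality: str,
    seed: int = 0,
    feature_config: PixelFeatureConfig | None = None,
    n_trees: int = 100,
) -> PixelClassifierModel:
    """Fit a random forest on scribbled pixels only.

    Raises a missing-class error if any class of the modality's class set has
    no scribbled pixel across the training images.
    """
    if modality == "dynamic":
        classes = DYNAMIC_CLASSES
    elif modality == "static":
        classes = STATIC_CLASSES
    else:
        raise ValueError("modality must be 'static' or 'dynamic'")
    feature_config = feature_config or PixelFeatureConfig()
    xs, ys = [], []
    n_channels = None
    for img, scrib in zip(images, scribbles):
        feats = pixel_feature_stack(img, feature_config)
        if n_channels is None:
            n_channels = 1 if np.asarray(img).ndim == 2 else np.asarray(img).shape[-1]
        sel = scrib > 0
        xs.append(feats[sel])
        ys.append(scrib[sel] - 1)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    present = set(np.unique(y).tolist())
    missing = [classes[i] for i in range(len(classes)) if i not in present]
    if missing:
        raise ValueError(f"no scribbled pixels for class(es): {missing}")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x, y)
    return PixelClassifierModel(
        modality=modality,
        classes=classes,
        forest=forest,
        feature_config=feature_config,
        n_channels=n_channels,
        training_manifest={
            "n_images": len(images),
            "scribble_counts": {classes[i]: int((y == i).sum()) for i in range(len(classes))},
            "seed": seed,
        },
    )


def apply_segmentation(image: np.ndarray, model: PixelClassifierModel) -> SegmentationMask:
    """Label every pixel with the forest's argmax class.

    Ties in the averaged tree votes resolve to the lowest class index.
    """
    image = np.asarray(image)
    n_channels = 1 if image.ndim == 2 else image.shape[-1]
    if n_channels != model.n_channels:
        raise ValueError(
            f"model expects {model.n_channels} channel(s), image has {n_channels}"
        )
    feats = pixel_feature_stack(image, model.feature_config)
    h, w, nf = feats.shape
    proba = model.forest.predict_proba(feats.reshape(-1, nf))
    # map forest class indices back to the full class set, then argmax
    full = np.zeros((proba.shape[0], len(model.classes)), dtype=proba.dtype)
    for col, cls_idx in enumerate(model.forest.classes_):
        full[:, int(cls_idx)] = proba[:, col]
    labels = np.argmax(full, axis=1).reshape(h, w).astype(np.int32)
    return SegmentationMask(
        labels=labels,
        class_map={i: c for i, c in enumerate(model.classes)},
        provenance="model",
    )


def mask_from_ground_truth(gt: GroundTruth, modality: str) -> SegmentationMask:
    """Ground-truth-derived mask, substitutable for a classifier mask.

    Lets downstream feature extraction be tested independently of classifier
    noise.
    """
    if modality == "dynamic":
        labels = np.full(gt.cell_mask.shape, 2, dtype=np.int32)  # not_cells
        ring = ndi.binary_dilation(gt.cell_mask, iterations=6) & ~gt.cell_mask
        labels[ring] = 1
        labels[gt.cell_mask] = 0
        class_map = {i: c for i, c in enumerate(DYNAMIC_CLASSES)}
    elif modality == "static":
        labels = np.full(gt.cell_mask.shape, 2, dtype=np.int32)  # cells/background
        ring = ndi.binary_dilation(gt.fiber_mask, iterations=4) & ~gt.fiber_mask
        labels[ring] = 1
        labels[gt.fiber_mask] = 0
        labels[gt.fat_mask] = 3
        class_map = {i: c for i, c in enumerate(STATIC_CLASSES)}
    else:
        raise ValueError("modality must be 'static' or 'dynamic'")
    return SegmentationMask(labels=labels, class_map=class_map, provenance="ground-truth")
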