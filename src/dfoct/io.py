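"""Readers and writers for on-disk artifacts.

Raw stacks are multi-page TIFF with acquisition metadata (sampling frequency,
pixel pitch) in a JSON sidecar; static images 16-bit TIFF; dynamic images
8-bit RGB PNG plus optional 32-bit float channel TIFFs; masks PNG label
images with a JSON class map; feature tables CSV; dataset manifests JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .features import FEATURE_NAMES, FeatureVector
from .reconstruct import DynamicImage, RawDynamicStack
from .segment import SegmentationMask

__all__ = [
    "read_stack",
    "write_stack",
    "write_image",
    "read_image",
    "write_dynamic_image",
    "write_mask",
    "read_mask",
    "write_feature_table",
    "read_feature_table",
    "write_manifest",
    "read_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: RawDynamicStack) -> Path:
    path = Path(path)
    # minisblack: frames are time points, never RGB planes
    tifffile.imwrite(path, stack.values, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"fs": stack.fs, "pixel_pitch_um": stack.pixel_pitch_um})
    )
    return path


def read_stack(path) -> RawDynamicStack:
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    meta = {"fs": 150.0, "pixel_pitch_um": 0.9}
    sc = _sidecar(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    else:
        warnings.warn(f"no metadata sidecar for {path}; using defaults", stacklevel=2)
    if values.shape[0] < 2:
        raise ValueError(f"{path} has a single page; not a dynamic stack")
    return RawDynamicStack(values=values, fs=meta["fs"], pixel_pitch_um=meta["pixel_pitch_um"])


def write_image(path, image: np.ndarray) -> Path:
    """Lossless write: float data to 32-bit TIFF, integer data as-is."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        if image.dtype.kind == "f":
            image = np.clip(image * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(path, image)
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_dynamic_image(path, image: DynamicImage, channels: bool = False) -> Path:
    """8-bit RGB render; with ``channels``, float TIFFs of H/S/V beside it."""
    path = Path(path)
    rgb8 = np.clip(image.rgb * 255.0, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb8)
    else:
        iio.imwrite(path, rgb8)
    if channels:
        for name, arr in (
            ("hue", image.hue),
            ("saturation", image.saturation),
            ("value_raw", image.value_raw),
        ):
            tifffile.imwrite(path.with_name(f"{path.stem}_{name}.tif"), arr.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"mode": image.mode, **image.metadata}))
    return path


def write_mask(path, mask: SegmentationMask) -> Path:
    path = Path(path)
    iio.imwrite(path, mask.labels.astype(np.uint8))
    _sidecar(path).write_text(
        json.dumps({"class_map": {str(k): v for k, v in mask.class_map.items()},
                    "provenance": mask.provenance})
    )
    return path


def read_mask(path) -> SegmentationMask:
    path = Path(path)
    labels = iio.imread(path).astype(np.int32)
    meta = json.loads(_sidecar(path).read_text())
    return SegmentationMask(
        labels=labels,
        class_map={int(k): v for k, v in meta["class_map"].items()},
        provenance=meta.get("provenance", "file"),
    )


def write_feature_table(path, vectors: list[FeatureVector], labels: list | None = None) -> Path:
    rows = []
    for i, v in enumerate(vectors):
        row = {"roi_id": v.roi_id, "sample_id": v.sample_id, **v.as_dict()}
        if labels is not None:
            row["label"] = labels[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} lacks columns: {missing[:3]}...")
    return df


def write_manifest(path, manifest: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"schema_version": 1, **manifest}, indent=2))
    return path


def read_manifest(path) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    for sample in manifest.get("samples", []):
        for roi in sample.get("rois", []):
            for key in ("stack", "static", "dynamic", "static_mask", "dynamic_mask"):
                if key in roi and roi[key] is not None:
                    p = root / roi[key]
                    if not p.exists():
                        raise FileNotFoundError(f"manifest references missing file: {p}")
    return manifest
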