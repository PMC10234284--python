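"""Engineered features from segmented static/dynamic image pairs.

From the dynamic modality the pipeline measures individual cells (8-connected
components of the ``cells`` class, area >= 20 px) and their mesoscale
organization (a 60-px box filter of the cell mask gives a local-density map;
8-connected regions where density exceeds 0.05 are "high cell density"
areas). From the static modality it measures collagen fibers (components of
the ``fibers`` class, area >= 100 px; mesoscale threshold 0.1), the intensity
statistics of the cell-region class, and the fat proportion.

Per-object measurements are summarized by mean and population standard
deviation, object orientations by circular statistics with period 180 deg
(orientation is axial). The result is a fixed, versioned 44-slot feature
vector; any measurement that cannot be made on an ROI (e.g. no high-density
region found) contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage import measure

from .reconstruct import DynamicImage
from .segment import SegmentationMask

__all__ = [
    "ObjectTable",
    "MesoscaleRegions",
    "FeatureVector",
    "FEATURE_NAMES",
    "CELL_MIN_AREA_PX",
    "FIBER_MIN_AREA_PX",
    "MESOSCALE_WINDOW_PX",
    "CELL_DENSITY_THRESHOLD",
    "FIBER_DENSITY_THRESHOLD",
    "extract_cells",
    "mesoscale_regions",
    "extract_fibers",
    "fat_and_cellregion_features",
    "assemble_feature_vector",
    "extract_roi_features",
]

CELL_MIN_AREA_PX = 20
FIBER_MIN_AREA_PX = 100
MESOSCALE_WINDOW_PX = 60
CELL_DENSITY_THRESHOLD = 0.05
FIBER_DENSITY_THRESHOLD = 0.1

SCHEMA_VERSION = 1


def _mean_sd(names_prefix: str, stats: tuple[str, ...]) -> list[str]:
    out = []
    for s in stats:
        out.append(f"{names_prefix}_{s}_mean")
        out.append(f"{names_prefix}_{s}_sd")
    return out


#: The frozen 44-name schema (order immutable across versions).
FEATURE_NAMES: tuple[str, ...] = tuple(
    ["cell_count", "cell_density"]
    + _mean_sd("cell", ("diameter", "eccentricity", "mean_r", "mean_g", "mean_b", "intensity_sd"))
    + ["cellregion_count"]
    + _mean_sd("cellregion", ("surface", "eccentricity"))
    + ["cells_outside_regions_count", "cells_outside_regions_fraction"]
    + ["fiber_count", "fiber_density"]
    + _mean_sd("fiber", ("area", "eccentricity", "orientation", "intensity"))
    + ["fiberregion_count"]
    + _mean_sd("fiberregion", ("area", "eccentricity", "intensity"))
    + ["static_cellregion_intensity_mean", "static_cellregion_intensity_sd"]
    + ["fat_proportion", "fatregion_count", "fatregion_area_mean", "fatregion_area_sd"]
)
assert len(FEATURE_NAMES) == 44


@dataclass
class ObjectTable:
    """Per-object measurements of one class (cells, fibers or fat regions)."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MesoscaleRegions:
    """High-local-density regions of an object mask."""

    density: np.ndarray
    region_mask: np.ndarray
    region_table: pd.DataFrame
    n_regions: int
    n_objects_outside: int
    fraction_objects_outside: float


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    roi_id: str = ""
    sample_id: str = ""
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (44,):
            raise ValueError("feature vector must have exactly 44 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(x)) if len(x) else 0.0


def _mean0(x: np.ndarray) -> float:
    return float(np.mean(x)) if len(x) else 0.0


def _orientation_deg(props) -> float:
    """Major-axis angle from the image x-axis, degrees in (-90, 90]."""
    deg = 90.0 - np.degrees(props.orientation)
    if deg > 90.0:
        deg -= 180.0
    return float(deg)


def circular_mean_sd_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    """Axial circular mean and sd (period 180 deg) of orientation angles."""
    if len(angles_deg) == 0:
        return 0.0, 0.0
    a = np.radians(np.asarray(angles_deg, dtype=np.float64)) * 2.0
    c, s = np.cos(a).mean(), np.sin(a).mean()
    mean = np.degrees(np.arctan2(s, c)) / 2.0
    if mean > 90.0:
        mean -= 180.0
    elif mean <= -90.0:
        mean += 180.0
    r = min(float(np.hypot(c, s)), 1.0)
    sd = 0.0 if r >= 1.0 else float(np.degrees(np.sqrt(-2.0 * np.log(max(r, 1e-300)))) / 2.0)
    return float(mean), sd


def _labeled_objects(mask: np.ndarray, min_area: int):
    lab = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(lab) if p.area >= min_area]
    return lab, props


def extract_cells(mask: SegmentationMask, dynamic_image: DynamicImage) -> ObjectTable:
    """Cells = 8-connected components of the dynamic ``cells`` class with
    area >= 20 px; per-cell morphology plus RGB intensity statistics from the
    reconstructed dynamic image."""
    cell_mask = mask.class_mask("cells")
    rgb = dynamic_image.rgb
    gray = rgb.mean(axis=-1)
    _, props = _labeled_objects(cell_mask, CELL_MIN_AREA_PX)
    rows = []
    for p in props:
        coords = tuple(p.coords.T)
        pix = rgb[coords]
        rows.append(
            {
                "area_px": int(p.area),
                "equivalent_diameter_px": float(p.equivalent_diameter_area),
                "eccentricity": float(p.eccentricity),
                "orientation_deg": _orientation_deg(p),
                "mean_r": float(pix[:, 0].mean()),
                "mean_g": float(pix[:, 1].mean()),
                "mean_b": float(pix[:, 2].mean()),
                "intensity_sd": float(gray[coords].std()),
                "centroid_y": float(p.centroid[0]),
                "centroid_x": float(p.centroid[1]),
            }
        )
    return ObjectTable(df=pd.DataFrame(rows))


def mesoscale_regions(
    object_mask: np.ndarray,
    window_px: int = MESOSCALE_WINDOW_PX,
    density_threshold: float = CELL_DENSITY_THRESHOLD,
    object_centroids: np.ndarray | None = None,
    intensity_image: np.ndarray | None = None,
) -> MesoscaleRegions:
    """High-density regions of an object mask.

    The local density is the mask box-filtered with a ``window_px``-wide
    square (zero padding, so near-border densities are conservatively low);
    regions are 8-connected components where density strictly exceeds the
    threshold. Objects (by centroid) falling outside every region are counted.
    """
    if window_px < 1:
        raise ValueError("window_px must be >= 1")
    if not 0 < density_threshold < 1:
        raise ValueError("density_threshold must be in (0, 1)")
    # box filter with zero padding; 'same' centering convention of
    # scipy.signal.convolve2d (window center at index (w-1)//2)
    kernel = np.ones((window_px, window_px), dtype=np.float64)
    counts = fftconvolve(np.asarray(object_mask, dtype=np.float64), kernel, mode="same")
    # window sums are integers; rounding removes FFT noise so thresholding
    # is exact arithmetic
    density = np.round(counts) / float(window_px**2)
    np.clip(density, 0.0, 1.0, out=density)
    region_mask = density > density_threshold
    lab = measure.label(region_mask, connectivity=2)
    props = measure.regionprops(lab, intensity_image=intensity_image)
    rows = []
    for p in props:
        row = {
            "area_px": int(p.area),
            "eccentricity": float(p.eccentricity),
        }
        if intensity_image is not None:
            row["mean_intensity"] = float(p.intensity_mean)
        rows.append(row)
    n_outside = 0
    frac_outside = 0.0
    if object_centroids is not None and len(object_centroids):
        cy = np.clip(np.round(object_centroids[:, 0]).astype(int), 0, region_mask.shape[0] - 1)
        cx = np.clip(np.round(object_centroids[:, 1]).astype(int), 0, region_mask.shape[1] - 1)
        inside = region_mask[cy, cx]
        n_outside = int((~inside).sum())
        frac_outside = n_outside / len(object_centroids)
    return MesoscaleRegions(
        density=density,
        region_mask=region_mask,
        region_table=pd.DataFrame(rows),
        n_regions=len(props),
        n_objects_outside=n_outside,
        fraction_objects_outside=frac_outside,
    )


def extract_fibers(
    mask: SegmentationMask, static_image: np.ndarray
) -> tuple[ObjectTable, MesoscaleRegions]:
    """Fibers = 8-connected components of the static ``fibers`` class with
    area >= 100 px; intensity taken from the raw static image. Mesoscale
    regions use the 60-px window at threshold 0.1."""
    fiber_mask = mask.class_mask("fibers")
    _, props = _labeled_objects(fiber_mask, FIBER_MIN_AREA_PX)
    rows = []
    for p in props:
        coords = tuple(p.coords.T)
        rows.append(
            {
                "area_px": int(p.area),
                "equivalent_diameter_px": float(p.equivalent_diameter_area),
                "eccentricity": float(p.eccentricity),
                "orientation_deg": _orientation_deg(p),
                "mean_intensity": float(np.asarray(static_image)[coords].mean()),
                "centroid_y": float(p.centroid[0]),
                "centroid_x": float(p.centroid[1]),
            }
        )
    table = ObjectTable(df=pd.DataFrame(rows))
    meso = mesoscale_regions(
        fiber_mask,
        window_px=MESOSCALE_WINDOW_PX,
        density_threshold=FIBER_DENSITY_THRESHOLD,
        intensity_image=np.asarray(static_image, dtype=np.float64),
    )
    return table, meso


def fat_and_cellregion_features(
    mask: SegmentationMask, static_image: np.ndarray
) -> tuple[float, ObjectTable, float, float]:
    """Fat proportion, fat-region table, and cell-region intensity stats.

    Fat proportion is fat pixels over total pixels; the intensity histogram
    of the static ``cells`` class is summarized by its mean and population sd.
    """
    static_image = np.asarray(static_image, dtype=np.float64)
    fat_mask = mask.class_mask("fat")
    fat_prop = float(fat_mask.mean())
    _, props = _labeled_objects(fat_mask, 1)
    rows = [
        {"area_px": int(p.area), "eccentricity": float(p.eccentricity)} for p in props
    ]
    fat_table = ObjectTable(df=pd.DataFrame(rows))
    cell_region = mask.class_mask("cells")
    if cell_region.any():
        vals = static_image[cell_region]
        ci_mean, ci_sd = float(vals.mean()), float(vals.std())
    else:
        ci_mean = ci_sd = 0.0
    return fat_prop, fat_table, ci_mean, ci_sd


def assemble_feature_vector(
    cells: ObjectTable,
    cell_meso: MesoscaleRegions,
    fibers: ObjectTable,
    fiber_meso: MesoscaleRegions,
    fat_proportion: float,
    fat_table: ObjectTable,
    cellregion_intensity_mean: float,
    cellregion_intensity_sd: float,
    cell_density: float,
    fiber_density: float,
    roi_id: str = "",
    sample_id: str = "",
) -> FeatureVector:
    """Assemble the frozen 44-slot vector; empty distributions contribute 0."""
    v: list[float] = []
    cdf = cells.df
    v += [float(len(cdf)), cell_density]
    for col in ("equivalent_diameter_px", "eccentricity", "mean_r", "mean_g", "mean_b", "intensity_sd"):
        x = cdf[col].to_numpy() if len(cdf) else np.array([])
        v += [_mean0(x), _pop_sd(x)]
    rt = cell_meso.region_table
    v.append(float(cell_meso.n_regions))
    for col in ("area_px", "eccentricity"):
        x = rt[col].to_numpy() if len(rt) else np.array([])
        v += [_mean0(x), _pop_sd(x)]
    v += [float(cell_meso.n_objects_outside), float(cell_meso.fraction_objects_outside)]

    fdf = fibers.df
    v += [float(len(fdf)), fiber_density]
    for col in ("area_px", "eccentricity", "orientation_deg", "mean_intensity"):
        x = fdf[col].to_numpy() if len(fdf) else np.array([])
        if col == "orientation_deg":
            m, s = circular_mean_sd_deg(x)
            v += [m, s]
        else:
            v += [_mean0(x), _pop_sd(x)]
    frt = fiber_meso.region_table
    v.append(float(fiber_meso.n_regions))
    for col in ("area_px", "eccentricity", "mean_intensity"):
        x = frt[col].to_numpy() if len(frt) else np.array([])
        v += [_mean0(x), _pop_sd(x)]

    v += [cellregion_intensity_mean, cellregion_intensity_sd]

    ft = fat_table.df
    x = ft["area_px"].to_numpy() if len(ft) else np.array([])
    v += [fat_proportion, float(len(ft)), _mean0(x), _pop_sd(x)]

    return FeatureVector(values=np.array(v), roi_id=roi_id, sample_id=sample_id)


def extract_roi_features(
    dynamic_mask: SegmentationMask,
    dynamic_image: DynamicImage,
    static_mask: SegmentationMask,
    static_image: np.ndarray,
    roi_id: str = "",
    sample_id: str = "",
) -> FeatureVector:
    """Full feature chain for one ROI pair."""
    cell_mask = dynamic_mask.class_mask("cells")
    cells = extract_cells(dynamic_mask, dynamic_image)
    centroids = (
        cells.df[["centroid_y", "centroid_x"]].to_numpy() if len(cells.df) else np.empty((0, 2))
    )
    cell_meso = mesoscale_regions(
        cell_mask,
        window_px=MESOSCALE_WINDOW_PX,
        density_threshold=CELL_DENSITY_THRESHOLD,
        object_centroids=centroids,
    )
    fibers, fiber_meso = extract_fibers(static_mask, static_image)
    fat_prop, fat_table, ci_mean, ci_sd = fat_and_cellregion_features(static_mask, static_image)
    return assemble_feature_vector(
        cells,
        cell_meso,
        fibers,
        fiber_meso,
        fat_prop,
        fat_table,
        ci_mean,
        ci_sd,
        cell_density=float(cell_mask.mean()),
        fiber_density=float(static_mask.class_mask("fibers").mean()),
        roi_id=roi_id,
        sample_id=sample_id,
    )
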