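"""Synthetic tissue phantoms for dynamic full-field OCT pipelines.

Real acquisitions pair a static image (extracellular matrix contrast: collagen
fibers, fat) with a raw dynamic stack whose per-pixel time series carry
intracellular motility. No clinical data ship with this package, so this
module plants geometric tissue phantoms with known ground truth:

* cells are ellipses whose pixels receive a sum of mean-reverting random
  walks (a discrete Ornstein-Uhlenbeck process) with a class-dependent
  correlation time, on top of white camera noise;
* fibers are oriented line segments whose orientations are drawn from an
  axial von Mises distribution (concentration ``kappa``; kappa -> 0 is
  disorganized);
* fat appears as dark discs.

Tumoral phantoms differ from healthy ones in cell density (higher), cell size
(larger), fiber organization (lower kappa) and intracellular correlation time
(shorter, i.e. faster dynamics), so that both the engineered-feature pipeline
and the CNN have a learnable but not trivial signal.

All randomness descends from one root seed through ``numpy.random.SeedSequence``
spawning, so identical seeds give bitwise-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reconstruct import RawDynamicStack

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "SampleSpec",
    "ROIRecord",
    "SampleDataset",
    "healthy_config",
    "tumoral_config",
    "simulate_pixel_timeseries",
    "generate_phantom_pair",
    "generate_sample_dataset",
]

#: number of superposed random walks per cell pixel signal
N_WALKS = 5

DEFAULT_N_FRAMES = 256
DEFAULT_FS = 150.0

# static-image intensity levels (arbitrary units in [0, 1])
_LEVEL_BG = 0.12
_LEVEL_CELL = 0.45
_LEVEL_FIBER = 0.85
_LEVEL_FAT = 0.04
_STATIC_NOISE_SD = 0.03


@dataclass(frozen=True)
class PhantomConfig:
    """Generative parameters of one phantom field of view.

    Lengths are micrometres unless suffixed ``_px``; densities are per mm^2
    (cells) or as pixel fractions (fibers, fat).
    """

    roi_size_px: int = 360
    pixel_pitch_um: float = 0.9
    class_label: str = "healthy"
    cell_density_per_mm2: float = 400.0
    cell_radius_um: tuple[float, float] = (5.0, 1.0)
    cell_eccentricity: tuple[float, float] = (0.0, 0.5)
    cell_dynamics_tau_s: float = 0.15
    dynamics_amplitude: float = 10.0
    fiber_density: float = 0.12
    fiber_orientation_kappa: float = 4.0
    fat_fraction: float = 0.08
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_size_px <= 0:
            raise ValueError("roi_size_px must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.class_label not in ("healthy", "tumoral"):
            raise ValueError("class_label must be 'healthy' or 'tumoral'")
        if self.cell_density_per_mm2 < 0:
            raise ValueError("cell_density_per_mm2 must be nonnegative")
        if self.cell_radius_um[0] <= 0 or self.cell_radius_um[1] <= 0:
            raise ValueError("cell_radius_um (mean, sd) must be positive")
        lo, hi = self.cell_eccentricity
        if not (0 <= lo <= hi < 1):
            raise ValueError("cell_eccentricity must be a range within [0, 1)")
        if self.cell_dynamics_tau_s <= 0:
            raise ValueError("cell_dynamics_tau_s must be positive")
        if self.dynamics_amplitude < 0:
            raise ValueError("dynamics_amplitude must be nonnegative")
        if not 0 <= self.fiber_density <= 1:
            raise ValueError("fiber_density must be in [0, 1]")
        if self.fiber_orientation_kappa < 0:
            raise ValueError("fiber_orientation_kappa must be nonnegative")
        if not 0 <= self.fat_fraction <= 1:
            raise ValueError("fat_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def roi_side_mm(self) -> float:
        return self.roi_size_px * self.pixel_pitch_um / 1000.0

    def n_cells(self) -> int:
        """Number of planted cells: round(density x ROI area in mm^2)."""
        return int(round(self.cell_density_per_mm2 * self.roi_side_mm**2))


def healthy_config(**overrides) -> PhantomConfig:
    """Default healthy phantom: sparse small organized cells, aligned fibers."""
    return replace(PhantomConfig(class_label="healthy"), **overrides)


def tumoral_config(**overrides) -> PhantomConfig:
    """Default tumoral phantom: 2.5x denser, 1.5x larger cells with faster
    dynamics; disorganized fibers (kappa 0.2 vs 4.0); little fat."""
    base = PhantomConfig(
        class_label="tumoral",
        cell_density_per_mm2=1000.0,
        cell_radius_um=(7.5, 1.5),
        cell_eccentricity=(0.3, 0.8),
        cell_dynamics_tau_s=0.05,
        dynamics_amplitude=14.0,
        fiber_density=0.08,
        fiber_orientation_kappa=0.2,
        fat_fraction=0.02,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Planted geometry of a phantom: masks plus object tables."""

    cell_mask: np.ndarray
    fiber_mask: np.ndarray
    fat_mask: np.ndarray
    cell_table: list = field(default_factory=list)  # dicts: centroid, radius_px, eccentricity
    fiber_table: list = field(default_factory=list)  # dicts: orientation_deg, width_px, length_px


@dataclass(frozen=True)
class SampleSpec:
    """Diagnosis structure of one specimen: healthy samples contain only
    healthy ROIs; tumoral samples contain at least one tumoral ROI but may
    include healthy-looking regions."""

    sample_id: str
    diagnosis: str
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.diagnosis not in ("healthy", "tumoral"):
            raise ValueError("diagnosis must be 'healthy' or 'tumoral'")
        if len(self.roi_labels) == 0:
            raise ValueError("sample needs at least one ROI")
        if self.diagnosis == "healthy" and any(l != "healthy" for l in self.roi_labels):
            raise ValueError("healthy samples must contain only healthy ROIs")
        if self.diagnosis == "tumoral" and not any(l == "tumoral" for l in self.roi_labels):
            raise ValueError("tumoral samples must contain at least one tumoral ROI")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


@dataclass(frozen=True)
class ROIRecord:
    sample_id: str
    roi_id: str
    true_label: str        # label of the generating phantom config
    inherited_label: str   # sample diagnosis passed down (the clinical ground truth)
    config: PhantomConfig


@dataclass
class SampleDataset:
    """ROIs grouped by sample. Phantom images are generated on demand via
    :func:`generate_phantom_pair` on each record's config."""

    samples: list[SampleSpec]
    rois: list[ROIRecord]
    seed: int

    def generate(self, roi: ROIRecord):
        return generate_phantom_pair(roi.config)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


# ---------------------------------------------------------------------------
# time-series synthesis


def _ou_walks(
    rng: np.random.Generator,
    n_series: int,
    n_frames: int,
    fs: float,
    tau_s: float,
    amplitude: float,
    n_walks: int = N_WALKS,
) -> np.ndarray:
    """Stationary sums of ``n_walks`` discrete Ornstein-Uhlenbeck processes.

    Each walk obeys x[t] = a x[t-1] + s*sqrt(1-a^2) eps with a = exp(-1/(fs tau)),
    so the lag-1 autocorrelation of the (noise-free) sum is exactly ``a`` and
    its stationary standard deviation is ``amplitude``.
    """
    a = np.exp(-1.0 / (fs * tau_s))
    s = amplitude / np.sqrt(n_walks)
    eps = rng.standard_normal((n_walks, n_series, n_frames))
    x = np.empty_like(eps)
    x[..., 0] = s * eps[..., 0]
    c = s * np.sqrt(1.0 - a * a)
    for t in range(1, n_frames):
        x[..., t] = a * x[..., t - 1] + c * eps[..., t]
    return x.sum(axis=0)


def simulate_pixel_timeseries(
    config: PhantomConfig,
    n_frames: int = DEFAULT_N_FRAMES,
    fs: float = DEFAULT_FS,
    region: str = "cell",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One pixel's raw time series.

    ``cell`` pixels carry a sum of mean-reverting random walks with
    correlation time ``cell_dynamics_tau_s`` plus white camera noise;
    ``background`` pixels carry white noise only.
    """
    if n_frames < 32:
        raise ValueError("n_frames must be >= 32")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if region not in ("cell", "background"):
        raise ValueError("region must be 'cell' or 'background'")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    series = rng.standard_normal(n_frames) * config.noise_sd
    if region == "cell":
        series = series + _ou_walks(
            rng, 1, n_frames, fs, config.cell_dynamics_tau_s, config.dynamics_amplitude
        )[0]
    return series


# ---------------------------------------------------------------------------
# geometry rasterization


def _plant_fat(rng: np.random.Generator, size: int, fat_fraction: float) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    if fat_fraction <= 0:
        return mask
    target = fat_fraction * size * size
    yy, xx = np.mgrid[0:size, 0:size]
    guard = 0
    while mask.sum() < target and guard < 10000:
        guard += 1
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(0.04, 0.12) * size
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return mask


def _plant_cells(
    rng: np.random.Generator, config: PhantomConfig, forbidden: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list]:
    size = config.roi_size_px
    n = config.n_cells()
    mask = np.zeros((size, size), dtype=bool)
    label = np.full((size, size), -1, dtype=np.int32)
    table: list[dict] = []
    yy, xx = np.mgrid[0:size, 0:size]
    mean_r, sd_r = config.cell_radius_um
    lo_e, hi_e = config.cell_eccentricity
    for i in range(n):
        # reject centers inside fat so tables stay consistent with masks
        for _ in range(50):
            cy, cx = rng.uniform(0, size, 2)
            if not forbidden[int(cy), int(cx)]:
                break
        r_um = max(rng.normal(mean_r, sd_r), 0.9 * config.pixel_pitch_um)
        r_px = r_um / config.pixel_pitch_um
        ecc = rng.uniform(lo_e, hi_e)
        theta = rng.uniform(0, np.pi)
        # equal-area semi-axes: a*b = r^2, e^2 = 1 - (b/a)^2
        ratio = np.sqrt(1.0 - ecc * ecc)  # b/a
        a_ax = r_px / np.sqrt(ratio)
        b_ax = r_px * np.sqrt(ratio)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0
        inside &= ~forbidden
        mask |= inside
        label[inside] = i
        table.append(
            {
                "centroid_y": cy,
                "centroid_x": cx,
                "radius_px": r_px,
                "eccentricity": ecc,
                "orientation_rad": theta,
            }
        )
    return mask, label, table


def _plant_fibers(
    rng: np.random.Generator, config: PhantomConfig, forbidden: np.ndarray
) -> tuple[np.ndarray, list]:
    size = config.roi_size_px
    mask = np.zeros((size, size), dtype=bool)
    table: list[dict] = []
    if config.fiber_density <= 0:
        return mask, table
    target = config.fiber_density * size * size
    yy, xx = np.mgrid[0:size, 0:size]
    guard = 0
    while mask.sum() < target and guard < 5000:
        guard += 1
        cy, cx = rng.uniform(0, size, 2)
        # axial orientation: von Mises on 2*theta, period pi
        theta = 0.5 * rng.vonmises(0.0, max(config.fiber_orientation_kappa, 1e-12))
        length = rng.uniform(0.3, 0.8) * size
        width = rng.uniform(2.0, 4.0)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        seg = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
        seg &= ~forbidden
        mask |= seg
        table.append(
            {
                "orientation_deg": np.degrees(theta),
                "length_px": length,
                "width_px": width,
                "centroid_y": cy,
                "centroid_x": cx,
            }
        )
    return mask, table


def generate_phantom_pair(
    config: PhantomConfig,
    n_frames: int = DEFAULT_N_FRAMES,
    fs: float = DEFAULT_FS,
) -> tuple[RawDynamicStack, np.ndarray, GroundTruth]:
    """Generate one (raw dynamic stack, static image, ground truth) triple.

    Overlaps resolve with priority fat > cell > fiber. The raw stack carries
    one shared random-walk signal per cell (coherent intracellular motion)
    plus independent per-pixel white noise; the static image encodes the
    matrix contrast as intensity levels (fibers bright, cells mid, fat dark).
    """
    size = config.roi_size_px
    root = np.random.SeedSequence(config.seed)
    geo_ss, dyn_ss, noise_ss, static_ss = root.spawn(4)
    geo = np.random.default_rng(geo_ss)

    fat = _plant_fat(geo, size, config.fat_fraction)
    cell_mask, cell_label, cell_table = _plant_cells(geo, config, fat)
    fiber_mask, fiber_table = _plant_fibers(geo, config, fat | cell_mask)
    gt = GroundTruth(
        cell_mask=cell_mask,
        fiber_mask=fiber_mask,
        fat_mask=fat,
        cell_table=cell_table,
        fiber_table=fiber_table,
    )

    # static image
    srng = np.random.default_rng(static_ss)
    static = np.full((size, size), _LEVEL_BG, dtype=np.float32)
    static[cell_mask] = _LEVEL_CELL
    static[fiber_mask] = _LEVEL_FIBER
    static[fat] = _LEVEL_FAT
    static += srng.normal(0.0, _STATIC_NOISE_SD, static.shape).astype(np.float32)
    static = np.clip(static, 0.0, 1.0)

    # raw stack: white noise everywhere, per-cell OU signal added on cell pixels
    nrng = np.random.default_rng(noise_ss)
    stack = nrng.standard_normal((n_frames, size, size), dtype=np.float32)
    stack *= np.float32(config.noise_sd)
    n_cells = len(cell_table)
    if n_cells and config.dynamics_amplitude > 0:
        drng = np.random.default_rng(dyn_ss)
        signals = _ou_walks(
            drng, n_cells, n_frames, fs, config.cell_dynamics_tau_s, config.dynamics_amplitude
        ).astype(np.float32)
        ys, xs = np.nonzero(cell_mask)
        lab = cell_label[ys, xs]
        stack[:, ys, xs] += signals[lab].T
    return (
        RawDynamicStack(values=stack, fs=fs, pixel_pitch_um=config.pixel_pitch_um),
        static,
        gt,
    )


# ---------------------------------------------------------------------------
# datasets


def generate_sample_dataset(
    n_healthy: int,
    n_tumoral: int,
    rois_per_sample: int = 11,
    healthy_cfg: PhantomConfig | None = None,
    tumoral_cfg: PhantomConfig | None = None,
    tumor_roi_fraction: float = 0.7,
    seed: int = 0,
) -> SampleDataset:
    """Build a multi-sample dataset with the clinical label structure.

    Healthy samples contain only healthy ROIs. In tumoral samples each ROI is
    tumoral with probability ``tumor_roi_fraction`` (at least one forced), so
    sample-inherited ROI labels carry realistic label noise while the true
    per-ROI labels remain recorded.
    """
    if n_healthy + n_tumoral <= 0:
        raise ValueError("at least one sample must be requested")
    if n_healthy < 0 or n_tumoral < 0 or rois_per_sample <= 0:
        raise ValueError("sample and ROI counts must be nonnegative/positive")
    if not 0 < tumor_roi_fraction <= 1:
        raise ValueError("tumor_roi_fraction must be in (0, 1]")
    healthy_cfg = healthy_cfg or healthy_config()
    tumoral_cfg = tumoral_cfg or tumoral_config()

    root = np.random.SeedSequence(seed)
    n_samples = n_healthy + n_tumoral
    children = root.spawn(1 + n_samples * rois_per_sample)
    label_rng = np.random.default_rng(children[0])
    samples: list[SampleSpec] = []
    rois: list[ROIRecord] = []
    roi_seed = 0
    for si in range(n_healthy + n_tumoral):
        diagnosis = "healthy" if si < n_healthy else "tumoral"
        sample_id = f"S{si:03d}"
        if diagnosis == "healthy":
            labels = ["healthy"] * rois_per_sample
        else:
            # deterministic count at random positions: keeps the label-noise
            # mechanism while guaranteeing the tumoral majority a resected
            # tumor specimen has
            n_tum = max(1, int(round(tumor_roi_fraction * rois_per_sample)))
            pos = label_rng.permutation(rois_per_sample)[:n_tum]
            labels = ["tumoral" if i in set(pos.tolist()) else "healthy"
                      for i in range(rois_per_sample)]
        samples.append(SampleSpec(sample_id=sample_id, diagnosis=diagnosis, roi_labels=tuple(labels)))
        for ri, lab in enumerate(labels):
            base = tumoral_cfg if lab == "tumoral" else healthy_cfg
            child = children[1 + roi_seed]
            cfg = replace(base, seed=int(child.generate_state(1)[0] % (2**31)))
            roi_seed += 1
            rois.append(
                ROIRecord(
                    sample_id=sample_id,
                    roi_id=f"{sample_id}_R{ri:02d}",
                    true_label=lab,
                    inherited_label=diagnosis,
                    config=cfg,
                )
            )
    return SampleDataset(samples=samples, rois=rois, seed=seed)
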