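"""Run configuration with the protocol's default constants."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class RunConfig:
    """Defaults pin the acquisition and analysis constants of the protocol:
    150 Hz sampling, cumulative-sum window 16, legacy bands 0/0.6/5.4/25 Hz,
    object area filters 20 px (cells) and 100 px (fibers), 60-px mesoscale
    window with thresholds 0.05 / 0.1, false-positive cost 3, normal-ratio
    threshold 0.5, 90th-percentile aggregation, and the SGD settings
    (lr 1e-4, momentum 0.8, batch 3, class weights 1.5/0.75, patience 100)."""

    seed: int = 0
    fs_hz: float = 150.0
    tau: int = 16
    band_edges_hz: tuple = (0.0, 0.6, 5.4, 25.0)
    welch_segment_length: int = 128
    welch_overlap: float = 0.5
    welch_window: str = "hann"
    cell_min_area_px: int = 20
    fiber_min_area_px: int = 100
    mesoscale_window_px: int = 60
    cell_density_threshold: float = 0.05
    fiber_density_threshold: float = 0.1
    fp_cost: float = 3.0
    cv_folds: int = 5
    ratio_threshold: float = 0.5
    nca_weight_threshold: float = 0.05
    aggregation_percentile: float = 90.0
    probability_threshold: float = 0.5
    lr: float = 1e-4
    momentum: float = 0.8
    batch_size: int = 3
    class_weight_healthy: float = 1.5
    class_weight_tumoral: float = 0.75
    patience: int = 100

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
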