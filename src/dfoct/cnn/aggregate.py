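"""Per-sample aggregation of ROI tumor probabilities.

A specimen's score is the 90th percentile (linear interpolation) of its ROI
probabilities — a compromise between the mean (which would dilute small
tumors in a bimodal distribution) and the maximum (oversensitive to one
false positive). The sample is called tumoral iff the score strictly
exceeds the probability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CnnSampleDiagnosis", "aggregate_sample_percentile"]


@dataclass
class CnnSampleDiagnosis:
    sample_id: str
    score: float
    predicted: str
    percentile: float
    threshold: float


def aggregate_sample_percentile(
    roi_probabilities: np.ndarray,
    sample_ids: list[str],
    percentile: float = 90.0,
    threshold: float = 0.5,
) -> list[CnnSampleDiagnosis]:
    probs = np.asarray(roi_probabilities, dtype=np.float64)
    sample_ids = list(sample_ids)
    order: list[str] = []
    for sid in sample_ids:
        if sid not in order:
            order.append(sid)
    out = []
    for sid in order:
        sel = np.array([s == sid for s in sample_ids])
        p = probs[sel]
        if len(p) == 0:
            warnings.warn(f"sample {sid} has no ROIs; excluded", stacklevel=2)
            continue
        score = float(np.percentile(p, percentile, method="linear"))
        out.append(
            CnnSampleDiagnosis(
                sample_id=sid,
                score=score,
                predicted="tumoral" if score > threshold else "healthy",
                percentile=percentile,
                threshold=threshold,
            )
        )
    return out
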