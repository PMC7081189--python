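"""Vessel flow quantification, Qp/Qs, classification, eligibility, BSA.

Flow through a fixed ROI is the sum of through-plane velocity over the
ROI's pixels times pixel area (cm/s x cm^2 = ml/s), integrated over the
cycle by the rectangle rule with uniform frame duration R-R / n_frames.
Net volume splits into forward (positive per-frame flow) and backward
(negative, reported as a positive magnitude) components.

Qp/Qs is pulmonary over systemic net volume; the normal range is 0.9-1.2
inclusive, above it left-to-right shunt, below it right-to-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import roi_to_mask
from .types import PhaseContrastSeries

NORMAL_RANGE = (0.9, 1.2)


@dataclass
class FlowResult:
    vessel_id: str
    flow_ml_s: np.ndarray  # per-frame flow
    frame_times_ms: np.ndarray
    net_volume_ml: float
    forward_volume_ml: float
    backward_volume_ml: float


@dataclass
class QpQsResult:
    qp_ml: float  # pulmonary net volume
    qs_ml: float  # systemic (aortic) net volume
    ratio: float
    classification: str  # "normal" | "left-to-right" | "right-to-left"


def flow_curve(
    series: PhaseContrastSeries, roi, vessel_id: str = "vessel"
) -> FlowResult:
    """Integrate through-plane flow over a fixed ROI across the cycle.

    ``roi`` is a boolean pixel mask or polygon (row, col vertices); the ROI
    does not track the vessel between frames.
    """
    m = roi_to_mask(roi, series.grid_shape)
    if not m.any():
        raise ValueError("ROI is empty")
    flow = series.velocity[:, m].sum(axis=1) * series.pixel_area_cm2  # ml/s
    dt = series.frame_duration_s
    net = float(flow.sum() * dt)
    forward = float(flow[flow > 0].sum() * dt)
    backward = float(-flow[flow < 0].sum() * dt)
    return FlowResult(
        vessel_id=vessel_id,
        flow_ml_s=flow,
        frame_times_ms=series.frame_times,
        net_volume_ml=net,
        forward_volume_ml=forward,
        backward_volume_ml=backward,
    )


def classify_qpqs(ratio: float, normal_range: tuple[float, float] = NORMAL_RANGE) -> str:
    """Label a Qp/Qs ratio against the normal range (bounds inclusive)."""
    lo, hi = normal_range
    if ratio > hi:
        return "left-to-right"
    if ratio < lo:
        return "right-to-left"
    return "normal"


def qpqs(pa: FlowResult, ao: FlowResult) -> QpQsResult:
    """Pulmonary-to-systemic flow ratio from the two vessels' net volumes."""
    if ao.net_volume_ml <= 0:
        raise ValueError(
            f"systemic net volume must be positive, got {ao.net_volume_ml:.2f} ml"
        )
    ratio = pa.net_volume_ml / ao.net_volume_ml
    return QpQsResult(
        qp_ml=pa.net_volume_ml,
        qs_ml=ao.net_volume_ml,
        ratio=ratio,
        classification=classify_qpqs(ratio),
    )


def rr_eligibility(rr_series, threshold: float = 0.10) -> bool:
    """Arrhythmia eligibility filter on beat-to-beat R-R intervals (ms).

    A subject is eligible iff, for every acquisition provided, the sample SD
    of the R-R intervals does not exceed ``threshold`` x the mean R-R
    ("exceeding" is strict: SD exactly at the threshold remains eligible).
    Accepts one series or a sequence of series (one per acquisition).
    """
    try:
        arr = np.asarray(rr_series, dtype=float)
    except (TypeError, ValueError):
        arr = None  # ragged: a sequence of unequal-length acquisitions
    if arr is not None and arr.ndim == 1:
        acquisitions = [arr]
    elif arr is not None and arr.ndim == 2:
        acquisitions = list(arr)
    else:
        acquisitions = [np.asarray(a, dtype=float) for a in rr_series]
    if not acquisitions or any(a.size == 0 for a in acquisitions):
        raise ValueError("empty R-R series")
    for rr in acquisitions:
        if rr.size < 2:
            raise ValueError("each acquisition needs >= 2 beats")
        if rr.std(ddof=1) > threshold * rr.mean():
            return False
    return True


def bsa_dubois(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2) by the DuBois & DuBois formula,

        BSA = 0.007184 * weight^0.425 * height^0.725 .
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725
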