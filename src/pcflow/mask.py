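"""Stationary-tissue detection for background fitting.

Mirrors the clinical workflow: include as much static tissue as possible by
raising a phase-deviation threshold, then exclude non-static structures
(lungs, major vessels) with regions of interest. "Phase deviation" is
implemented as the temporal standard deviation of each pixel's velocity
across the cardiac cycle, thresholded in cm/s; a magnitude gate relative to
the image median removes air/lung pixels whose phase is pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import PCFlowError, PhaseContrastSeries


class EmptyMaskError(PCFlowError):
    """All pixels were excluded; the message names the responsible criterion."""


def point_in_polygon(point, polygon) -> bool:
    """Even-odd (crossing-number) point-in-polygon test.

    Points exactly on a polygon edge or vertex count as inside. Coordinates
    are (row, col) pairs; the polygon is implicitly closed.

    Raises
    ------
    ValueError
        if the polygon has fewer than 3 vertices or is degenerate (all
        vertices collinear, enclosing no area).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) vertex array")
    v0 = poly - poly[0]
    cross = v0[:, 0] * v0[-1, 1] - v0[:, 1] * v0[-1, 0]
    # degenerate iff every vertex is collinear with the first edge direction
    d = poly[1] - poly[0]
    if np.allclose(np.abs(v0[:, 0] * d[1] - v0[:, 1] * d[0]), 0.0, atol=1e-12):
        raise ValueError("degenerate polygon: vertices are collinear")
    del cross

    p = np.asarray(point, dtype=float)
    a = poly
    b = np.roll(poly, -1, axis=0)

    # boundary test: point on any closed segment counts as inside
    ab = b - a
    ap = p[None, :] - a
    cross_e = ab[:, 0] * ap[:, 1] - ab[:, 1] * ap[:, 0]
    dot = ab[:, 0] * ap[:, 0] + ab[:, 1] * ap[:, 1]
    len2 = (ab**2).sum(axis=1)
    scale = np.sqrt(np.maximum(len2, 1e-300))
    on_edge = (np.abs(cross_e) / scale <= 1e-9) & (dot >= -1e-9) & (dot <= len2 + 1e-9)
    if on_edge.any():
        return True

    # crossing count on a ray in +col direction; half-open vertex rule
    r, c = p
    ar, ac = a[:, 0], a[:, 1]
    br, bc = b[:, 0], b[:, 1]
    straddles = (ar > r) != (br > r)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_at = ac + (r - ar) * (bc - ac) / (br - ar)
    crossings = int(np.count_nonzero(straddles & (c_at > c)))
    return crossings % 2 == 1


def polygon_to_mask(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean pixel mask (pixel centers tested)."""
    poly = np.asarray(polygon, dtype=float)
    out = np.zeros(shape, dtype=bool)
    r0 = max(int(np.floor(poly[:, 0].min())), 0)
    r1 = min(int(np.ceil(poly[:, 0].max())), shape[0] - 1)
    c0 = max(int(np.floor(poly[:, 1].min())), 0)
    c1 = min(int(np.ceil(poly[:, 1].max())), shape[1] - 1)
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            out[r, c] = point_in_polygon((float(r), float(c)), poly)
    return out


def roi_to_mask(roi, shape: tuple[int, int]) -> np.ndarray:
    """Accept an ROI as either a boolean pixel mask or a polygon vertex list."""
    arr = np.asarray(roi)
    if arr.dtype == bool:
        if arr.shape != shape:
            raise ValueError(f"ROI mask shape {arr.shape} != grid {shape}")
        return arr
    return polygon_to_mask(arr, shape)


@dataclass
class StaticMask:
    """Boolean static-tissue map plus the settings that produced it."""

    mask: np.ndarray
    phase_deviation_threshold: float  # cm/s
    magnitude_threshold: float  # fraction of the median time-averaged magnitude
    exclusion_rois: list = field(default_factory=list)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def detect_static(
    series: PhaseContrastSeries,
    phase_deviation_threshold: float = 2.0,
    magnitude_threshold: float = 0.3,
    exclusion_rois=(),
    vessel_rois=(),
) -> StaticMask:
    """Identify stationary-tissue pixels.

    A pixel is static iff all of:

    * temporal SD of its velocity <= ``phase_deviation_threshold`` (cm/s),
    * time-averaged magnitude >= ``magnitude_threshold`` x the median
      time-averaged magnitude over the whole image,
    * it lies outside every exclusion ROI and every vessel ROI (vessels are
      always excluded, with or without user-drawn exclusions).

    ROIs may be polygons (vertex arrays, (row, col), 0-based) or boolean
    masks; the simulator's label maps plug in directly as the latter.

    Raises
    ------
    EmptyMaskError
        naming the criterion that removed the last pixels.
    """
    if phase_deviation_threshold <= 0 or magnitude_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if series.n_frames < 2:
        raise ValueError("need >= 2 frames to measure phase deviation")

    shape = series.grid_shape
    temporal_sd = series.velocity.std(axis=0, ddof=1)
    mean_mag = series.magnitude.mean(axis=0)

    mask = temporal_sd <= phase_deviation_threshold
    if not mask.any():
        raise EmptyMaskError(
            "phase-deviation threshold "
            f"({phase_deviation_threshold} cm/s) excluded every pixel"
        )
    mask &= mean_mag >= magnitude_threshold * np.median(mean_mag)
    if not mask.any():
        raise EmptyMaskError(
            f"magnitude threshold ({magnitude_threshold} x median) "
            "excluded the remaining pixels"
        )
    for roi in exclusion_rois:
        mask &= ~roi_to_mask(roi, shape)
    if not mask.any():
        raise EmptyMaskError("exclusion ROIs excluded the remaining pixels")
    for roi in vessel_rois:
        mask &= ~roi_to_mask(roi, shape)
    if not mask.any():
        raise EmptyMaskError("vessel ROIs excluded the remaining pixels")

    return StaticMask(
        mask=mask,
        phase_deviation_threshold=phase_deviation_threshold,
        magnitude_threshold=magnitude_threshold,
        exclusion_rois=list(exclusion_rois),
    )


def maximize_static(
    series: PhaseContrastSeries,
    initial_threshold: float = 2.0,
    magnitude_threshold: float = 0.3,
    exclusion_rois=(),
    vessel_rois=(),
    target_fraction: float = 0.3,
    growth: float = 1.25,
    max_threshold: float = 25.0,
) -> StaticMask:
    """Maximize the static tissue included by raising the phase-deviation
    threshold, as done interactively in clinical software: starting from
    ``initial_threshold`` the threshold grows geometrically until the mask
    covers ``target_fraction`` of the grid (or ``max_threshold`` is hit, in
    which case the largest mask found is returned)."""
    threshold = initial_threshold
    best: StaticMask | None = None
    n_total = series.grid_shape[0] * series.grid_shape[1]
    while threshold <= max_threshold:
        try:
            cand = detect_static(
                series, threshold, magnitude_threshold, exclusion_rois, vessel_rois
            )
        except EmptyMaskError:
            cand = None
        if cand is not None and (best is None or cand.n_pixels > best.n_pixels):
            best = cand
        if best is not None and best.n_pixels >= target_fraction * n_total:
            return best
        threshold *= growth
    if best is None:
        raise EmptyMaskError(
            f"no non-empty static mask up to phase-deviation threshold "
            f"{max_threshold} cm/s"
        )
    return best
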