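"""Core containers shared by every stage of the pipeline.

Unit conventions, fixed once for the whole package:

* velocity      cm/s (through-plane; positive = designated forward direction)
* pixel spacing mm (isotropic in-plane)
* R-R interval  ms
* volumes       ml (= cm^3)
* coordinates   0-based (row, col) pixel indices
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PCFlowError(Exception):
    """Base class for package errors."""


class AliasingError(PCFlowError):
    """A velocity exceeds the velocity-encoding limit (VENC)."""


class MetadataError(PCFlowError):
    """A required metadata field is missing or inconsistent."""


@dataclass
class PhaseContrastSeries:
    """A velocity-encoded cine series: one cardiac cycle of paired
    magnitude and velocity images.

    Attributes
    ----------
    magnitude : (n_frames, rows, cols) float array, arbitrary scanner units.
    velocity : (n_frames, rows, cols) float array, cm/s.
    venc : velocity-encoding limit, cm/s; |true velocity| must stay below it.
    pixel_spacing : in-plane pixel size, mm (isotropic).
    rr_interval : cardiac cycle duration, ms.
    meta : free-form provenance (seed, applied corrections, ...).
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    venc: float
    pixel_spacing: float
    rr_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.magnitude.ndim != 3 or self.velocity.ndim != 3:
            raise ValueError("magnitude and velocity must be (n_frames, rows, cols)")
        if self.magnitude.shape != self.velocity.shape:
            raise MetadataError(
                "magnitude/velocity frame-count or grid mismatch: "
                f"{self.magnitude.shape} vs {self.velocity.shape}"
            )
        if self.venc <= 0 or self.pixel_spacing <= 0 or self.rr_interval <= 0:
            raise ValueError("venc, pixel_spacing and rr_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.velocity.shape[1:]

    @property
    def frame_duration_s(self) -> float:
        """Uniform frame duration R-R / n_frames, seconds (retrospective gating)."""
        return self.rr_interval / self.n_frames / 1000.0

    @property
    def frame_times(self) -> np.ndarray:
        """Frame onset times within the cycle, ms."""
        return np.arange(self.n_frames) * (self.rr_interval / self.n_frames)

    @property
    def pixel_area_cm2(self) -> float:
        return (self.pixel_spacing / 10.0) ** 2

    def copy(self) -> "PhaseContrastSeries":
        return PhaseContrastSeries(
            magnitude=self.magnitude.copy(),
            velocity=self.velocity.copy(),
            venc=self.venc,
            pixel_spacing=self.pixel_spacing,
            rr_interval=self.rr_interval,
            meta=dict(self.meta),
        )
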