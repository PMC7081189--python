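"""Background phase (velocity offset) estimation and subtraction.

The central computation: average the velocity images over the cardiac
cycle, fit a first- or second-order 2D polynomial to the time-averaged
velocity of the stationary-tissue pixels by ordinary least squares, and
subtract the fitted surface from every frame. Stationary tissue has zero
true mean velocity, so whatever smooth surface it carries is the
eddy-current background offset.

The fit operates on velocity in cm/s (phase and velocity differ only by
the constant VENC/pi, so the two formulations are equivalent) and on
normalized centered coordinates x, y in [-1, 1] for conditioning;
coefficients are therefore grid-size specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask import StaticMask
from .simulate import normalized_coords, polynomial_surface
from .types import AliasingError, PhaseContrastSeries

_NCOEF = {1: 3, 2: 6}


@dataclass
class BackgroundModel:
    """Fitted background surface.

    coefficients follow the monomial basis [1, x, y] (order 1) or
    [1, x, y, x^2, y^2, xy] (order 2) in normalized coordinates, cm/s.
    """

    order: int
    coefficients: np.ndarray
    n_static_pixels: int
    residual_rms: float  # cm/s
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order not in _NCOEF:
            raise ValueError("order must be 1 or 2")
        if self.coefficients.size != _NCOEF[self.order]:
            raise ValueError("coefficient count does not match order")

    def surface(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape if shape is not None else self.grid_shape
        return polynomial_surface(self.coefficients, self.order, shape)


def time_average_velocity(series: PhaseContrastSeries) -> np.ndarray:
    """Per-pixel arithmetic mean of velocity over all frames (cm/s)."""
    if series.n_frames < 1:
        raise ValueError("series has no frames")
    return series.velocity.mean(axis=0)


def _design_matrix(mask: np.ndarray, order: int) -> np.ndarray:
    xx, yy = normalized_coords(mask.shape)
    x = xx[mask]
    y = yy[mask]
    cols = [np.ones_like(x), x, y]
    if order == 2:
        cols += [x**2, y**2, x * y]
    return np.column_stack(cols)


def fit_background(
    mean_velocity: np.ndarray, mask: StaticMask | np.ndarray, order: int = 1
) -> BackgroundModel:
    """Ordinary least-squares polynomial fit to static-pixel mean velocity.

    Minimizes sum over static pixels of (v_mean - p(x, y))^2 for the
    monomial basis of the requested order. Unweighted: the mask's magnitude
    gate has already removed low-SNR pixels.

    Raises
    ------
    ValueError
        if the mask holds fewer pixels than coefficients, or the design is
        rank-deficient (e.g. all static pixels collinear).
    """
    if order not in _NCOEF:
        raise ValueError("order must be 1 or 2")
    m = mask.mask if isinstance(mask, StaticMask) else np.asarray(mask, dtype=bool)
    if m.shape != mean_velocity.shape:
        raise ValueError("mask / velocity-map shape mismatch")
    ncoef = _NCOEF[order]
    n = int(m.sum())
    if n < ncoef:
        raise ValueError(f"order-{order} fit needs >= {ncoef} static pixels, got {n}")

    X = _design_matrix(m, order)
    v = mean_velocity[m]
    coeffs, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < ncoef:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {ncoef}): "
            "static pixels do not constrain the basis"
        )
    resid = v - X @ coeffs
    return BackgroundModel(
        order=order,
        coefficients=coeffs,
        n_static_pixels=n,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        grid_shape=mean_velocity.shape,
    )


def apply_correction(
    series: PhaseContrastSeries, model: BackgroundModel
) -> PhaseContrastSeries:
    """Subtract the fitted background surface from every frame.

    Magnitude images are untouched; the applied model is recorded in the
    output metadata.
    """
    if model.grid_shape != series.grid_shape:
        raise ValueError(
            f"model grid {model.grid_shape} does not match series {series.grid_shape}"
        )
    surface = model.surface()
    out = series.copy()
    out.velocity = out.velocity - surface[None, :, :]
    out.meta["background_correction"] = {
        "order": model.order,
        "coefficients": model.coefficients.tolist(),
        "n_static_pixels": model.n_static_pixels,
        "residual_rms_cm_s": model.residual_rms,
    }
    return out


def velocity_from_phase(phase: np.ndarray, venc: float) -> np.ndarray:
    """Standard PC-MRI scaling v = phi * VENC / pi for phi in [-pi, pi]."""
    phase = np.asarray(phase, dtype=float)
    if venc <= 0:
        raise ValueError("venc must be positive")
    if np.any(np.abs(phase) > np.pi * (1 + 1e-12)):
        raise AliasingError("phase outside [-pi, pi]: data are aliased")
    return phase * venc / np.pi
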