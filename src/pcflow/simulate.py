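"""Synthetic phase-contrast cine phantoms with known ground truth.

The phantom emulates a through-plane velocity-mapping slice at the level of
the great vessels: two circular vessels (ascending aorta, main pulmonary
artery) carrying pulsatile parabolic flow, surrounding stationary
chest-wall/mediastinal tissue (bright magnitude, zero true velocity), two
lung fields (dark magnitude, hence noisy phase), and an additive spatially
smooth background velocity offset — the eddy-current phase error that the
correction stage exists to remove — modelled as a first- or second-order 2D
polynomial in normalized image coordinates.

Every phantom carries a ground-truth sidecar (true background coefficients,
true per-vessel net volumes, true Qp/Qs, label maps) so each downstream
stage can be tested against exact expected values.

Discretization convention: a vessel is the set of pixels whose *centers*
fall within its radius, with no partial-volume weighting, and the flow
module integrates over the identical pixel set — so in the absence of noise
and background the measured net volume equals the ground truth to float
precision, isolating background-correction error in all tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import AliasingError, PhaseContrastSeries

# label-map codes (disjoint partition of the grid)
LABEL_STATIC = 0
LABEL_AORTA = 1
LABEL_PA = 2
LABEL_LUNG = 3

#: magnitude of stationary tissue in arbitrary units; lung magnitude is
#: snr_lung/snr_tissue of this, vessel blood is slightly brighter.
TISSUE_MAGNITUDE = 1.0
VESSEL_MAGNITUDE = 1.2


@dataclass(frozen=True)
class VesselSpec:
    """One circular vessel with pulsatile parabolic through-plane flow.

    The temporal waveform is a half-sinusoid systolic ejection occupying
    ``systolic_fraction`` of the cycle plus a small constant diastolic
    component (``diastolic_level`` relative to the systolic peak), scaled so
    the discrete cycle integral hits ``stroke_volume_ml`` exactly.
    """

    name: str
    center: tuple[float, float]  # (row, col), pixels
    radius_mm: float
    stroke_volume_ml: float
    systolic_fraction: float = 0.4
    diastolic_level: float = 0.05


@dataclass(frozen=True)
class LungSpec:
    """An elliptical low-magnitude lung/air region."""

    center: tuple[float, float]  # (row, col), pixels
    semi_axes: tuple[float, float]  # (rows, cols), pixels


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one synthetic acquisition.

    Defaults mirror a routine 1.5T retrospectively gated protocol: VENC
    150 cm/s (within the usual 100-200 cm/s window), 5 mm-class in-plane
    resolution scaled to a 96x96 grid, 30 reconstructed phases, and
    magnitude SNR 30 for tissue (free-breathing with three-fold averaging).
    """

    grid_rows: int = 96
    grid_cols: int = 96
    pixel_spacing: float = 2.0  # mm
    n_frames: int = 30
    rr_interval: float = 1000.0  # ms
    venc: float = 150.0  # cm/s
    vessels: tuple[VesselSpec, ...] = (
        VesselSpec("aorta", center=(52.0, 40.0), radius_mm=14.0, stroke_volume_ml=90.0),
        VesselSpec("pa", center=(42.0, 58.0), radius_mm=13.5, stroke_volume_ml=90.0),
    )
    lungs: tuple[LungSpec, ...] = (
        LungSpec(center=(48.0, 14.0), semi_axes=(30.0, 11.0)),
        LungSpec(center=(48.0, 82.0), semi_axes=(30.0, 11.0)),
    )
    background_order: int = 1
    background_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0)  # cm/s, normalized coords
    snr_tissue: float = 30.0
    snr_lung: float = 3.0
    rr_variability: float = 0.02  # fractional SD of the beat-to-beat R-R series
    n_beats: int = 117
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid too small")
        if self.background_order not in (0, 1, 2):
            raise ValueError("background_order must be 0, 1 or 2")
        ncoef = {0: 1, 1: 3, 2: 6}[self.background_order]
        if len(self.background_coeffs) != ncoef:
            raise ValueError(
                f"order {self.background_order} needs {ncoef} coefficients, "
                f"got {len(self.background_coeffs)}"
            )
        if self.snr_tissue <= 0 or self.snr_lung <= 0:
            raise ValueError("SNRs must be positive")
        for v in self.vessels:
            if v.radius_mm <= 2.0 * self.pixel_spacing:
                raise ValueError(
                    f"vessel '{v.name}' radius {v.radius_mm} mm must exceed "
                    f"2 x pixel spacing ({2 * self.pixel_spacing} mm)"
                )
            if not 0.0 < v.systolic_fraction < 1.0:
                raise ValueError("systolic_fraction must lie in (0, 1)")
            if v.stroke_volume_ml <= 0:
                raise ValueError("stroke volume must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows and downstream stages must recover."""

    background_order: int
    background_coeffs: np.ndarray  # cm/s, normalized coordinates
    net_volumes_ml: dict[str, float]  # per vessel, noise- and background-free
    qpqs: float  # PA net / aortic net
    labels: np.ndarray  # (rows, cols) int map of LABEL_* codes
    rr_series: np.ndarray  # beat-to-beat R-R intervals, ms
    peak_velocities: dict[str, float] = field(default_factory=dict)  # cm/s

    def vessel_mask(self, name: str) -> np.ndarray:
        code = {"aorta": LABEL_AORTA, "pa": LABEL_PA}[name]
        return self.labels == code

    @property
    def static_mask(self) -> np.ndarray:
        return self.labels == LABEL_STATIC

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels == LABEL_LUNG


def normalized_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized centered coordinates x (columns), y (rows) in [-1, 1].

    All polynomial background surfaces are expressed in these coordinates;
    coefficients are therefore not comparable across grid sizes.
    """
    rows, cols = shape
    y = (np.arange(rows) - (rows - 1) / 2.0) / ((rows - 1) / 2.0)
    x = (np.arange(cols) - (cols - 1) / 2.0) / ((cols - 1) / 2.0)
    xx, yy = np.meshgrid(x, y)
    return xx, yy


def polynomial_surface(
    coeffs: np.ndarray | tuple[float, ...], order: int, shape: tuple[int, int]
) -> np.ndarray:
    """Evaluate a background polynomial on the pixel grid.

    Basis order: [1, x, y] for order 1, plus [x^2, y^2, xy] for order 2;
    order 0 is the constant term alone.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    xx, yy = normalized_coords(shape)
    terms = [np.ones(shape), xx, yy, xx**2, yy**2, xx * yy]
    ncoef = {0: 1, 1: 3, 2: 6}[order]
    if coeffs.size != ncoef:
        raise ValueError(f"order {order} expects {ncoef} coefficients")
    out = np.zeros(shape)
    for c, t in zip(coeffs, terms):
        out += c * t
    return out


def _waveform(params: PhantomParams, vessel: VesselSpec) -> np.ndarray:
    """Unnormalized temporal shape s(t_k) sampled at frame onsets."""
    t = np.arange(params.n_frames) / params.n_frames  # fraction of cycle
    fs = vessel.systolic_fraction
    s = np.where(t < fs, np.sin(np.pi * t / fs), vessel.diastolic_level)
    return s


def _vessel_profile(
    params: PhantomParams, vessel: VesselSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel membership mask and parabolic shape factor 1 - (r/R)^2."""
    rr, cc = np.meshgrid(
        np.arange(params.grid_rows, dtype=float),
        np.arange(params.grid_cols, dtype=float),
        indexing="ij",
    )
    radius_px = vessel.radius_mm / params.pixel_spacing
    dist2 = (rr - vessel.center[0]) ** 2 + (cc - vessel.center[1]) ** 2
    inside = dist2 <= radius_px**2
    profile = np.where(inside, 1.0 - dist2 / radius_px**2, 0.0)
    return inside, profile


def _lung_mask(params: PhantomParams) -> np.ndarray:
    rr, cc = np.meshgrid(
        np.arange(params.grid_rows, dtype=float),
        np.arange(params.grid_cols, dtype=float),
        indexing="ij",
    )
    mask = np.zeros((params.grid_rows, params.grid_cols), dtype=bool)
    for lung in params.lungs:
        (r0, c0), (ar, ac) = lung.center, lung.semi_axes
        mask |= ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    return mask


def noise_free_peak_velocity(params: PhantomParams) -> float:
    """Largest noise-free |velocity| the parameters imply (cm/s):
    max over vessels of the systolic-peak centerline velocity, plus the
    worst-case |background| (sum of absolute coefficients, since the
    normalized monomials are bounded by 1)."""
    peak = 0.0
    pixel_area = (params.pixel_spacing / 10.0) ** 2
    dt = params.rr_interval / params.n_frames / 1000.0
    for vessel in params.vessels:
        _, profile = _vessel_profile(params, vessel)
        s = _waveform(params, vessel)
        denom = pixel_area * dt * s.sum() * profile.sum()
        peak = max(peak, vessel.stroke_volume_ml / denom * s.max())
    return peak + float(np.abs(params.background_coeffs).sum())


def adapt_venc(
    params: PhantomParams, candidates=(100.0, 150.0, 200.0, 250.0, 300.0)
) -> PhantomParams:
    """Pick the lowest candidate VENC that avoids aliasing (5% headroom),
    emulating the clinical 'VENC adapted to avoid aliasing' protocol step."""
    need = 1.05 * noise_free_peak_velocity(params)
    for venc in candidates:
        if venc > need:
            return replace(params, venc=venc)
    return replace(params, venc=float(candidates[-1]))


def make_phantom(params: PhantomParams) -> tuple[PhaseContrastSeries, GroundTruth]:
    """Simulate one velocity-encoded cine acquisition.

    Returns the series (magnitude + velocity stacks with metadata) and its
    ground truth. The velocity image is

        v(x, y, t) = parabolic vessel flow + background polynomial
                     + zero-mean Gaussian noise, SD = venc / (pi * SNR * m_rel)

    with m_rel the local magnitude relative to stationary tissue — the
    standard reciprocal magnitude-SNR behaviour of PC-MRI phase noise, which
    makes lung phase noisy and is why lungs are excluded from static-tissue
    fitting.

    Raises
    ------
    AliasingError
        if any noise-free velocity (flow + background) exceeds VENC.
    ValueError
        for degenerate geometry (vessels overlapping each other or a lung).
    """
    params.validate()
    shape = (params.grid_rows, params.grid_cols)
    rng = np.random.default_rng(params.seed)

    lung = _lung_mask(params)
    labels = np.full(shape, LABEL_STATIC, dtype=int)
    labels[lung] = LABEL_LUNG

    pixel_area = (params.pixel_spacing / 10.0) ** 2  # cm^2
    dt = params.rr_interval / params.n_frames / 1000.0  # s

    clean = np.zeros((params.n_frames,) + shape)
    net_volumes: dict[str, float] = {}
    peak_velocities: dict[str, float] = {}
    vessel_codes = {"aorta": LABEL_AORTA, "pa": LABEL_PA}

    for vessel in params.vessels:
        inside, profile = _vessel_profile(params, vessel)
        if not inside.any():
            raise ValueError(f"vessel '{vessel.name}' covers no pixel centers")
        if (labels[inside] != LABEL_STATIC).any():
            raise ValueError(
                f"vessel '{vessel.name}' overlaps a lung or another vessel"
            )
        labels[inside] = vessel_codes.get(vessel.name, LABEL_AORTA)

        s = _waveform(params, vessel)
        # peak scaled so the discrete cycle integral equals the target SV
        denom = pixel_area * dt * s.sum() * profile.sum()
        v_peak = vessel.stroke_volume_ml / denom
        clean += v_peak * s[:, None, None] * profile[None, :, :]
        peak_velocities[vessel.name] = v_peak * s.max()

        # ground-truth net volume by the same discrete sum flow_curve uses
        net = float((v_peak * np.outer(s, profile[inside].ravel())).sum() * pixel_area * dt)
        net_volumes[vessel.name] = net

    background = polynomial_surface(
        params.background_coeffs, params.background_order, shape
    )
    noise_free = clean + background[None, :, :]
    vmax = float(np.abs(noise_free).max())
    if vmax > params.venc:
        raise AliasingError(
            f"noise-free velocity {vmax:.1f} cm/s exceeds VENC {params.venc} cm/s"
        )

    magnitude_base = np.full(shape, TISSUE_MAGNITUDE)
    magnitude_base[labels == LABEL_LUNG] = (
        TISSUE_MAGNITUDE * params.snr_lung / params.snr_tissue
    )
    magnitude_base[(labels == LABEL_AORTA) | (labels == LABEL_PA)] = VESSEL_MAGNITUDE

    if math.isinf(params.snr_tissue):
        velocity = noise_free
        magnitude = np.broadcast_to(magnitude_base, (params.n_frames,) + shape).copy()
    else:
        m_rel = magnitude_base / TISSUE_MAGNITUDE
        vel_sd = params.venc / (np.pi * params.snr_tissue * m_rel)
        velocity = noise_free + rng.normal(
            0.0, 1.0, size=(params.n_frames,) + shape
        ) * vel_sd[None, :, :]
        mag_sd = TISSUE_MAGNITUDE / params.snr_tissue
        magnitude = magnitude_base[None, :, :] + rng.normal(
            0.0, mag_sd, size=(params.n_frames,) + shape
        )

    rr_series = params.rr_interval * (
        1.0 + params.rr_variability * rng.standard_normal(params.n_beats)
    )

    series = PhaseContrastSeries(
        magnitude=magnitude,
        velocity=velocity,
        venc=params.venc,
        pixel_spacing=params.pixel_spacing,
        rr_interval=params.rr_interval,
        meta={"seed": params.seed, "simulated": True},
    )
    truth = GroundTruth(
        background_order=params.background_order,
        background_coeffs=np.asarray(params.background_coeffs, dtype=float),
        net_volumes_ml=net_volumes,
        qpqs=net_volumes["pa"] / net_volumes["aorta"],
        labels=labels,
        rr_series=rr_series,
        peak_velocities=peak_velocities,
    )
    return series, truth


# ---------------------------------------------------------------------------
# cohorts

#: Per-coefficient SD (cm/s) of the order-2 background polynomial drawn for
#: each synthetic acquisition. Calibrated by Monte-Carlo so that with the
#: default Qp/Qs distribution N(1.0, 0.04) about 18% of uncorrected ratios
#: fall outside the 0.9-1.2 normal range, matching the clinical prevalence
#: the pipeline is meant to demonstrate correction against.
DEFAULT_BACKGROUND_COEFF_SD = 0.98


@dataclass
class CohortSubject:
    """One synthetic patient: paired aorta-plane and PA-plane acquisitions."""

    subject_id: str
    params_aorta: PhantomParams  # acquisition targeting the aorta
    params_pa: PhantomParams  # acquisition targeting the pulmonary artery
    true_qpqs: float
    true_net_volumes_ml: dict[str, float]
    covariates: dict[str, float]


def make_cohort(
    n: int,
    qpqs_mean: float = 1.0,
    qpqs_sd: float = 0.04,
    background_coeff_sd: float = DEFAULT_BACKGROUND_COEFF_SD,
    seed: int = 0,
    base_params: PhantomParams | None = None,
    background_order: int = 2,
) -> list[CohortSubject]:
    """Draw a synthetic cohort of paired aorta/PA acquisitions.

    True Qp/Qs is drawn from N(qpqs_mean, qpqs_sd) truncated to (0.5, 2.0);
    aortic stroke volume from N(93, 22) ml truncated to (40, 180) (typical
    adult clinical spread); each acquisition receives an independent
    background polynomial with i.i.d. N(0, background_coeff_sd) coefficients,
    emulating eddy-current offsets that differ between the two slice
    prescriptions. Deterministic under a fixed seed.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    if qpqs_sd < 0 or background_coeff_sd < 0:
        raise ValueError("SDs must be >= 0")
    if not 0.5 < qpqs_mean < 2.0:
        raise ValueError("qpqs_mean must lie inside the truncation range (0.5, 2.0)")
    base = base_params if base_params is not None else PhantomParams()
    ncoef = {0: 1, 1: 3, 2: 6}[background_order]
    rng = np.random.default_rng(seed)

    subjects: list[CohortSubject] = []
    for i in range(n):
        while True:
            q = rng.normal(qpqs_mean, qpqs_sd) if qpqs_sd > 0 else qpqs_mean
            if 0.5 < q < 2.0:
                break
        while True:
            sv_ao = rng.normal(93.0, 22.0)
            if 40.0 < sv_ao < 180.0:
                break
        sv_pa = q * sv_ao

        vessels = tuple(
            replace(
                v,
                stroke_volume_ml=sv_ao if v.name == "aorta" else sv_pa,
            )
            for v in base.vessels
        )
        coeffs_ao = tuple(rng.normal(0.0, background_coeff_sd, size=ncoef))
        coeffs_pa = tuple(rng.normal(0.0, background_coeff_sd, size=ncoef))
        seed_ao = int(rng.integers(0, 2**31 - 1))
        seed_pa = int(rng.integers(0, 2**31 - 1))

        params_ao = adapt_venc(
            replace(
                base,
                vessels=vessels,
                background_order=background_order,
                background_coeffs=coeffs_ao,
                seed=seed_ao,
            )
        )
        params_pa = adapt_venc(
            replace(
                base,
                vessels=vessels,
                background_order=background_order,
                background_coeffs=coeffs_pa,
                seed=seed_pa,
            )
        )

        weight = float(np.clip(rng.normal(79.0, 18.0), 40.0, 160.0))
        height = float(np.clip(rng.normal(174.0, 9.0), 140.0, 210.0))
        covariates = {
            "sex_male": float(rng.random() < 0.62),
            "age_yr": float(np.clip(rng.normal(50.0, 16.0), 18.0, 90.0)),
            "weight_kg": weight,
            "height_cm": height,
        }
        subjects.append(
            CohortSubject(
                subject_id=f"S{i:03d}",
                params_aorta=params_ao,
                params_pa=params_pa,
                true_qpqs=q,
                true_net_volumes_ml={"aorta": sv_ao, "pa": sv_pa},
                covariates=covariates,
            )
        )
    return subjects
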