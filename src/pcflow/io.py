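"""On-disk formats: series containers, ROI files, run configuration, DICOM.

A synthetic series is stored as one directory per acquisition:

    <dir>/magnitude.npy   (n_frames, rows, cols) float
    <dir>/velocity.npy    (n_frames, rows, cols) float, cm/s
    <dir>/meta.json       venc_cm_s, pixel_spacing_mm, rr_interval_ms, ...
    <dir>/labels.npy      optional ground-truth label map
    <dir>/truth.json      optional ground-truth sidecar

ROI polygons travel as CSV vertex lists with an explanatory header
(0-based row, col pixel coordinates). Run configurations are YAML and
round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulate import GroundTruth
from .types import MetadataError, PhaseContrastSeries

_REQUIRED_META = ("venc_cm_s", "pixel_spacing_mm", "rr_interval_ms", "n_frames")


def write_series(
    path, series: PhaseContrastSeries, truth: GroundTruth | None = None
) -> Path:
    """Write a series (and optionally its ground truth) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "magnitude.npy", series.magnitude)
    np.save(path / "velocity.npy", series.velocity)
    meta = {
        "venc_cm_s": series.venc,
        "pixel_spacing_mm": series.pixel_spacing,
        "rr_interval_ms": series.rr_interval,
        "n_frames": series.n_frames,
        "frame_times_ms": series.frame_times.tolist(),
        **{f"x_{k}": v for k, v in series.meta.items()},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        np.save(path / "labels.npy", truth.labels)
        sidecar = {
            "background_order": truth.background_order,
            "background_coeffs_cm_s": truth.background_coeffs.tolist(),
            "net_volumes_ml": truth.net_volumes_ml,
            "qpqs": truth.qpqs,
            "rr_series_ms": truth.rr_series.tolist(),
            "peak_velocities_cm_s": truth.peak_velocities,
        }
        (path / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path) -> PhaseContrastSeries:
    """Read a series directory back; raises naming any missing metadata."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise MetadataError(f"no meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise MetadataError(f"metadata field {key!r} missing from {meta_path}")
    magnitude = np.load(path / "magnitude.npy")
    velocity = np.load(path / "velocity.npy")
    if magnitude.shape[0] != meta["n_frames"] or velocity.shape[0] != meta["n_frames"]:
        raise MetadataError(
            f"frame count mismatch: meta says {meta['n_frames']}, "
            f"arrays have {magnitude.shape[0]}/{velocity.shape[0]}"
        )
    extra = {k[2:]: v for k, v in meta.items() if k.startswith("x_")}
    return PhaseContrastSeries(
        magnitude=magnitude,
        velocity=velocity,
        venc=meta["venc_cm_s"],
        pixel_spacing=meta["pixel_spacing_mm"],
        rr_interval=meta["rr_interval_ms"],
        meta=extra,
    )


def read_truth(path) -> GroundTruth:
    path = Path(path)
    sidecar = json.loads((path / "truth.json").read_text())
    return GroundTruth(
        background_order=sidecar["background_order"],
        background_coeffs=np.asarray(sidecar["background_coeffs_cm_s"], dtype=float),
        net_volumes_ml=sidecar["net_volumes_ml"],
        qpqs=sidecar["qpqs"],
        labels=np.load(path / "labels.npy"),
        rr_series=np.asarray(sidecar["rr_series_ms"], dtype=float),
        peak_velocities=sidecar.get("peak_velocities_cm_s", {}),
    )


# ---------------------------------------------------------------------------
# ROI polygon files

ROI_HEADER = "# ROI polygon vertices: 0-based pixel coordinates, columns row,col"


def write_roi(path, polygon) -> Path:
    path = Path(path)
    poly = np.asarray(polygon, dtype=float)
    lines = [ROI_HEADER, "row,col"]
    lines += [f"{r},{c}" for r, c in poly]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_roi(path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("row"):
            continue
        r, c = line.split(",")
        rows.append((float(r), float(c)))
    if len(rows) < 3:
        raise ValueError(f"ROI file {path} holds fewer than 3 vertices")
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything an end-to-end cohort run needs, YAML round-trippable."""

    out_dir: str = "pcflow_out"
    seed: int = 0
    n_subjects: int = 91
    qpqs_mean: float = 1.0
    qpqs_sd: float = 0.04
    background_coeff_sd: float | None = None  # None -> simulator default
    background_order: int = 2
    phase_deviation_threshold: float = 2.0  # cm/s
    magnitude_threshold: float = 0.3  # fraction of median magnitude
    correction_orders: tuple[int, ...] = (1, 2)
    normal_range: tuple[float, float] = (0.9, 1.2)

    def __post_init__(self) -> None:
        if self.phase_deviation_threshold <= 0 or self.magnitude_threshold <= 0:
            raise ValueError("thresholds must be positive")
        self.correction_orders = tuple(self.correction_orders)
        self.normal_range = tuple(self.normal_range)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# DICOM ingestion (optional path; synthetic containers are the primary format)


def read_dicom_series(
    magnitude_files, phase_files, venc_cm_s: float, rr_interval_ms: float | None = None
):
    """Assemble a series from paired magnitude/phase DICOM files.

    Phase values are rescaled with the stored RescaleSlope/Intercept and
    interpreted as angle in [-pi, pi] mapped linearly to [-venc, venc]
    (v = phi * VENC / pi). VENC is passed explicitly because its DICOM
    encoding is vendor-private. Frames are ordered as provided.
    """
    import pydicom

    from .correct import velocity_from_phase

    mags, phases = [], []
    spacing = None
    rr = rr_interval_ms
    for mf, pf in zip(magnitude_files, phase_files, strict=True):
        md = pydicom.dcmread(mf)
        pdset = pydicom.dcmread(pf)
        spacing = float(md.PixelSpacing[0]) if "PixelSpacing" in md else spacing
        if rr is None and "NominalInterval" in md and md.NominalInterval:
            rr = float(md.NominalInterval)
        mags.append(md.pixel_array.astype(float))
        raw = pdset.pixel_array.astype(float)
        slope = float(getattr(pdset, "RescaleSlope", 1.0))
        intercept = float(getattr(pdset, "RescaleIntercept", 0.0))
        phases.append(raw * slope + intercept)
    if spacing is None:
        raise MetadataError("metadata field 'PixelSpacing' missing from DICOM")
    if rr is None:
        raise MetadataError(
            "R-R interval unavailable: pass rr_interval_ms or provide NominalInterval"
        )
    velocity = velocity_from_phase(np.stack(phases), venc_cm_s)
    return PhaseContrastSeries(
        magnitude=np.stack(mags),
        velocity=velocity,
        venc=venc_cm_s,
        pixel_spacing=spacing,
        rr_interval=rr,
        meta={"source": "dicom"},
    )
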