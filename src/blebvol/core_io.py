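"""Core data model and on-disk formats.

The package works on four kinds of records:

* :class:`OCTVolume` — a 3D stack of voxel reflectivities, indexed
  ``(b_scan y, a_scan x, depth z)``, together with the acquisition metadata
  needed for calibration (nominal lateral scan lengths, scan angle, axial
  range in air).
* :class:`VoxelCalibration` — the physical size of one voxel along each axis
  (mm/pixel) with the standard deviations of the two lateral pitches.
* :class:`BoundaryTrace` — per-column upper/lower axial boundary indices
  delimiting a segmented region (the bleb, or the visible half of a
  calibration ball).
* :class:`VolumeMeasurement` — a volume in μL with its uncertainty and
  provenance.

Volumes are stored as multi-page TIFF (one page per B-scan) or NIfTI-1, with
a sidecar JSON next to the image file carrying the acquisition metadata.
Traces are plain CSV; calibrations and measurements are JSON with units in
the key names.  Intensities are held internally as float32 in [0, 1];
integer files are rescaled by their dtype maximum on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvariantError, ShapeError

__all__ = [
    "OCTVolume",
    "VoxelCalibration",
    "BoundaryTrace",
    "VolumeMeasurement",
    "read_volume",
    "write_volume",
    "read_boundaries",
    "write_boundaries",
    "read_calibration",
    "write_calibration",
    "read_measurement",
    "write_measurement",
]

_TRACE_COLUMNS = ["b_scan_index", "a_scan_index", "upper_z", "lower_z"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OCTVolume:
    """A 3D OCT intensity stack plus acquisition metadata.

    ``intensities`` is indexed ``(b_scan, a_scan, depth)`` — the slow scan
    axis first, matching the acquisition order of B-scans made of A-scans.
    """

    intensities: np.ndarray
    nominal_scan_x_mm: float
    nominal_scan_y_mm: float
    scan_angle_deg: float = 0.0
    axial_range_air_mm: float = 7.4
    volume_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ShapeError(f"intensities must be 3D (b, a, z); got ndim={arr.ndim}")
        if min(arr.shape) < 1:
            raise ShapeError(f"all dimension counts must be >= 1; got shape {arr.shape}")
        if arr.dtype != np.float32:
            arr = arr.astype(np.float32)
        if not np.isfinite(arr).all():
            raise InvariantError("intensities must all be finite")
        lo, hi = float(arr.min()), float(arr.max())
        if lo < 0.0 or hi > 1.0:
            raise InvariantError(f"intensities must lie in [0, 1]; got range [{lo}, {hi}]")
        for name in ("nominal_scan_x_mm", "nominal_scan_y_mm", "axial_range_air_mm"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"{name} must be > 0")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_depth(self) -> int:
        return self.intensities.shape[2]

    def metadata(self) -> dict:
        return {
            "nominal_scan_x_mm": self.nominal_scan_x_mm,
            "nominal_scan_y_mm": self.nominal_scan_y_mm,
            "scan_angle_deg": self.scan_angle_deg,
            "axial_range_air_mm": self.axial_range_air_mm,
            "volume_id": self.volume_id,
        }


@dataclass(frozen=True)
class VoxelCalibration:
    """Physical voxel pitches in mm/pixel, with lateral-pitch SDs.

    ``source`` records provenance: ``"nominal"`` (pitch = nominal scan length
    divided by pixel count) or ``"en_face_object"`` (pitch calibrated from an
    en-face image of an object of known diameter).
    """

    x_pitch_mm: float
    y_pitch_mm: float
    z_pitch_mm: float
    x_pitch_sd_mm: float = 0.0
    y_pitch_sd_mm: float = 0.0
    medium_refractive_index: float = 1.336
    source: str = "nominal"

    def __post_init__(self) -> None:
        for name in ("x_pitch_mm", "y_pitch_mm", "z_pitch_mm"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"{name} must be > 0")
        for name in ("x_pitch_sd_mm", "y_pitch_sd_mm"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")
        if self.medium_refractive_index < 1:
            raise InvariantError("medium_refractive_index must be >= 1")
        if self.source not in ("nominal", "en_face_object"):
            raise InvariantError(f"unknown calibration source {self.source!r}")


@dataclass(frozen=True)
class BoundaryTrace:
    """Per-(B-scan, A-scan) upper/lower axial boundary indices.

    ``entries`` has one row per traced image column with 0-based integer
    columns ``b_scan_index, a_scan_index, upper_z, lower_z``; a voxel belongs
    to the traced region iff ``upper_z <= z <= lower_z`` (closed interval, so
    a degenerate column with upper == lower counts one pixel).
    """

    entries: pd.DataFrame
    semicircle_doubled: bool = False

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"trace is missing columns {missing}")
        df = df[_TRACE_COLUMNS].reset_index(drop=True)
        if len(df):
            if not all(np.issubdtype(df[c].dtype, np.integer) for c in _TRACE_COLUMNS):
                try:
                    as_int = df.astype(np.int64)
                except (ValueError, TypeError) as exc:
                    raise InvariantError(f"trace indices must be integers: {exc}") from exc
                if not (as_int.to_numpy() == df.to_numpy()).all():
                    raise InvariantError("trace indices must be integers")
                df = as_int
            else:
                df = df.astype(np.int64)
            neg = df[(df[_TRACE_COLUMNS] < 0).any(axis=1)]
            if len(neg):
                raise InvariantError(f"negative index in trace rows {list(neg.index[:5])}")
            bad = df[df["upper_z"] > df["lower_z"]]
            if len(bad):
                row = int(bad.index[0])
                raise InvariantError(
                    f"upper_z > lower_z at row {row} "
                    f"(b={bad.iloc[0]['b_scan_index']}, a={bad.iloc[0]['a_scan_index']})"
                )
            dup = df.duplicated(subset=["b_scan_index", "a_scan_index"])
            if dup.any():
                raise InvariantError(
                    f"duplicate (b_scan_index, a_scan_index) at rows {list(df.index[dup][:5])}"
                )
        object.__setattr__(self, "entries", df)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_arrays(
        cls,
        b_scan_index: Sequence[int],
        a_scan_index: Sequence[int],
        upper_z: Sequence[int],
        lower_z: Sequence[int],
        semicircle_doubled: bool = False,
    ) -> "BoundaryTrace":
        df = pd.DataFrame(
            {
                "b_scan_index": np.asarray(b_scan_index, dtype=np.int64),
                "a_scan_index": np.asarray(a_scan_index, dtype=np.int64),
                "upper_z": np.asarray(upper_z, dtype=np.int64),
                "lower_z": np.asarray(lower_z, dtype=np.int64),
            }
        )
        return cls(entries=df, semicircle_doubled=semicircle_doubled)

    def validate_against(self, n_bscans: int, n_ascans: int, n_depth: int) -> None:
        """Check all indices fit inside a volume of the given extents."""
        df = self.entries
        if not len(df):
            return
        if int(df["b_scan_index"].max()) >= n_bscans:
            raise InvariantError("b_scan_index outside volume extents")
        if int(df["a_scan_index"].max()) >= n_ascans:
            raise InvariantError("a_scan_index outside volume extents")
        if int(df["lower_z"].max()) >= n_depth:
            raise InvariantError("lower_z outside volume depth")


@dataclass(frozen=True)
class VolumeMeasurement:
    """A measured volume in μL (1 μL ≡ 1 mm³) with uncertainty and provenance."""

    volume_ul: float
    total_pixels: int
    abs_uncertainty_ul: float = 0.0
    rel_uncertainty_pct: float = 0.0
    calibration_source: str = "nominal"
    volume_id: str = ""

    def __post_init__(self) -> None:
        if self.volume_ul < 0:
            raise InvariantError("volume_ul must be >= 0")
        if self.total_pixels < 0:
            raise InvariantError("total_pixels must be >= 0")


# ---------------------------------------------------------------------------
# volume files
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write an :class:`OCTVolume` as multi-page TIFF or NIfTI-1 plus sidecar JSON.

    The format is chosen from the file suffix (.tif/.tiff vs .nii/.nii.gz).
    Intensities are written as float32, so a write/read round trip is
    bit-identical.  Returns the sidecar path.
    """
    path = Path(path)
    name = path.name
    if name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, volume.intensities)
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(volume.intensities, np.eye(4)), path)
    else:
        raise FormatError(f"unsupported volume format for {path.name!r} (use TIFF or NIfTI)")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(volume.metadata(), indent=2))
    return sidecar


def read_volume(path: str | Path) -> OCTVolume:
    """Read a multi-page TIFF or NIfTI volume with its sidecar JSON metadata.

    Integer payloads are rescaled to [0, 1] by their dtype maximum; float
    payloads must already lie in [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar.name} for {path.name}")
    meta = json.loads(sidecar.read_text())
    name = path.name
    if name.endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    elif name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(path).dataobj)
    else:
        raise FormatError(f"unsupported volume format for {path.name!r}")
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ShapeError(f"volume payload must be 3D; got ndim={arr.ndim}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(np.float32)
    try:
        return OCTVolume(
            intensities=arr,
            nominal_scan_x_mm=float(meta["nominal_scan_x_mm"]),
            nominal_scan_y_mm=float(meta["nominal_scan_y_mm"]),
            scan_angle_deg=float(meta.get("scan_angle_deg", 0.0)),
            axial_range_air_mm=float(meta["axial_range_air_mm"]),
            volume_id=str(meta.get("volume_id", path.stem)),
        )
    except KeyError as exc:
        raise FormatError(f"sidecar {sidecar.name} lacks required key {exc}") from exc


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def read_boundaries(path: str | Path) -> BoundaryTrace:
    """Read a boundary trace CSV (header: b_scan_index,a_scan_index,upper_z,lower_z)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such trace file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace CSV {path.name} is missing columns {missing}")
    doubled = bool(df["semicircle_doubled"].iloc[0]) if ("semicircle_doubled" in df.columns and len(df)) else False
    return BoundaryTrace(entries=df[_TRACE_COLUMNS], semicircle_doubled=doubled)


def write_boundaries(trace: BoundaryTrace, path: str | Path) -> None:
    df = trace.entries.copy()
    if trace.semicircle_doubled:
        df["semicircle_doubled"] = True
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibrations and measurements (JSON)
# ---------------------------------------------------------------------------

def write_calibration(cal: VoxelCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cal), indent=2))


def read_calibration(path: str | Path) -> VoxelCalibration:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such calibration file: {path}")
    data = json.loads(path.read_text())
    try:
        return VoxelCalibration(**data)
    except TypeError as exc:
        raise FormatError(f"bad calibration file {path.name}: {exc}") from exc


def write_measurement(meas: VolumeMeasurement, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(meas), indent=2))


def read_measurement(path: str | Path) -> VolumeMeasurement:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such measurement file: {path}")
    data = json.loads(path.read_text())
    try:
        return VolumeMeasurement(**data)
    except TypeError as exc:
        raise FormatError(f"bad measurement file {path.name}: {exc}") from exc
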