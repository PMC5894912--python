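"""Voxel-pitch calibration.

Lateral (X, Y) pitches come from an en-face projection of an object of known
diameter: the object's diameter is measured in pixels on the en-face image,
and pitch = known diameter in mm / measured diameter in pixels.  Repeating
the pixel measurement gives a sample SD, which propagates first-order into a
pitch SD.  The axial (Z) pitch is a property of the scanner: the axial range
in air divided by the number of depth samples, converted from optical to
geometric path by the refractive index of the imaging medium (balanced salt
solution, n ≈ 1.336 at 1060 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from skimage import measure as _skmeasure

from .core_io import OCTVolume, VoxelCalibration
from .exceptions import AmbiguityError, InvariantError

__all__ = [
    "EnFaceImage",
    "DiameterMeasurementSet",
    "project_en_face",
    "measure_diameter_px",
    "calibrate_lateral",
    "compute_z_pitch",
    "nominal_calibration",
    "build_calibration",
]


@dataclass(frozen=True)
class EnFaceImage:
    """Top-down 2D projection of an OCT volume over depth.

    ``pixels[y, x]`` with y the B-scan index and x the A-scan index.
    """

    pixels: np.ndarray
    projection: str = "max"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InvariantError("en-face image must be 2D")
        if self.projection not in ("max", "mean"):
            raise InvariantError(f"unknown projection {self.projection!r}")
        object.__setattr__(self, "pixels", arr.astype(np.float32))


@dataclass(frozen=True)
class DiameterMeasurementSet:
    """Repeated pixel-diameter measurements of a known-size object along one axis."""

    axis: str                      # "x" | "y"
    diameters_px: List[float]
    known_diameter_mm: float

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise InvariantError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if len(self.diameters_px) == 0:
            raise InvariantError("diameters_px must be non-empty")
        if any(d <= 0 for d in self.diameters_px):
            raise InvariantError("all measured diameters must be > 0")
        if self.known_diameter_mm <= 0:
            raise InvariantError("known_diameter_mm must be > 0")


def project_en_face(volume: OCTVolume, projection: str = "max") -> EnFaceImage:
    """Collapse depth: pixel (y, x) = max (or mean) intensity over z at that column."""
    if projection == "max":
        img = volume.intensities.max(axis=2)
    elif projection == "mean":
        img = volume.intensities.mean(axis=2)
    else:
        raise InvariantError(f"unknown projection {projection!r}")
    return EnFaceImage(pixels=img, projection=projection)


def measure_diameter_px(
    image: EnFaceImage,
    axis: str,
    threshold: float | None = None,
    min_blob_px: int = 9,
) -> int:
    """Pixel diameter of the single supra-threshold blob along one axis.

    The image is thresholded (default: 50% of the peak intensity, a symmetric
    edge estimator for a bright object on a dark field), connected components
    smaller than ``min_blob_px`` are discarded as noise specks, and exactly
    one blob must remain.  The returned extent is measured along the row
    (axis "x") or column (axis "y") through the blob centroid:
    last supra-threshold index − first + 1.
    """
    if axis not in ("x", "y"):
        raise InvariantError(f"axis must be 'x' or 'y', got {axis!r}")
    px = image.pixels
    thr = 0.5 * float(px.max()) if threshold is None else float(threshold)
    mask = px >= thr
    if not mask.any():
        raise AmbiguityError("no supra-threshold structure in the en-face image")
    labels = _skmeasure.label(mask, connectivity=2)
    props = [p for p in _skmeasure.regionprops(labels) if p.area >= min_blob_px]
    if len(props) == 0:
        raise AmbiguityError("no supra-threshold blob above the minimum size")
    if len(props) > 1:
        raise AmbiguityError(f"expected one blob, found {len(props)}")
    blob = props[0]
    blob_mask = labels == blob.label
    cy, cx = blob.centroid
    if axis == "x":
        line = blob_mask[int(round(cy)), :]
    else:
        line = blob_mask[:, int(round(cx))]
    idx = np.nonzero(line)[0]
    if idx.size == 0:  # centroid row misses the blob (pathological shapes)
        raise AmbiguityError("blob centroid line contains no supra-threshold pixels")
    return int(idx[-1] - idx[0] + 1)


def calibrate_lateral(
    measurements_x: DiameterMeasurementSet,
    measurements_y: DiameterMeasurementSet,
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Lateral pitches (mm/pixel) with SDs from repeated diameter measurements.

    pitch = known diameter / mean(measured pixel diameters).  The SD follows
    by first-order (delta-method) propagation of the sample SD s of the
    repeated measurements through the ratio: sd(pitch) ≈ d·s/mean².  A single
    measurement yields sd = 0 with a warning.

    Returns ``((x_pitch, x_sd), (y_pitch, y_sd))``.
    """
    if measurements_x.known_diameter_mm != measurements_y.known_diameter_mm:
        raise InvariantError("X and Y measurement sets must share the known diameter")

    def one(ms: DiameterMeasurementSet) -> Tuple[float, float]:
        d = np.asarray(ms.diameters_px, dtype=float)
        mean = float(d.mean())
        pitch = ms.known_diameter_mm / mean
        if d.size < 2:
            warnings.warn(
                f"single diameter measurement on axis {ms.axis!r}: pitch SD reported as 0",
                stacklevel=3,
            )
            return pitch, 0.0
        s = float(d.std(ddof=1))
        sd = ms.known_diameter_mm * s / mean**2
        return pitch, sd

    return one(measurements_x), one(measurements_y)


def compute_z_pitch(
    axial_range_air_mm: float,
    n_depth: int,
    medium_refractive_index: float = 1.336,
) -> float:
    """Axial pitch in mm of geometric depth per pixel.

    The scanner's axial range is an optical path length in air; dividing by
    the number of depth samples gives the optical pitch, and dividing by the
    medium's refractive index converts to geometric depth in the medium.
    """
    if axial_range_air_mm <= 0:
        raise InvariantError("axial_range_air_mm must be > 0")
    if n_depth < 1:
        raise InvariantError("n_depth must be >= 1")
    if medium_refractive_index < 1:
        raise InvariantError("refractive index must be >= 1")
    return axial_range_air_mm / n_depth / medium_refractive_index


def nominal_calibration(
    volume: OCTVolume, medium_refractive_index: float = 1.336
) -> VoxelCalibration:
    """Pitches from the nominal scan lengths and pixel counts alone."""
    return VoxelCalibration(
        x_pitch_mm=volume.nominal_scan_x_mm / volume.n_ascans,
        y_pitch_mm=volume.nominal_scan_y_mm / volume.n_bscans,
        z_pitch_mm=compute_z_pitch(
            volume.axial_range_air_mm, volume.n_depth, medium_refractive_index
        ),
        medium_refractive_index=medium_refractive_index,
        source="nominal",
    )


def build_calibration(
    measurements_x: DiameterMeasurementSet,
    measurements_y: DiameterMeasurementSet,
    axial_range_air_mm: float,
    n_depth: int,
    medium_refractive_index: float = 1.336,
) -> VoxelCalibration:
    """Assemble a full :class:`VoxelCalibration` from en-face object measurements."""
    (xp, xsd), (yp, ysd) = calibrate_lateral(measurements_x, measurements_y)
    return VoxelCalibration(
        x_pitch_mm=xp,
        y_pitch_mm=yp,
        z_pitch_mm=compute_z_pitch(axial_range_air_mm, n_depth, medium_refractive_index),
        x_pitch_sd_mm=xsd,
        y_pitch_sd_mm=ysd,
        medium_refractive_index=medium_refractive_index,
        source="en_face_object",
    )
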