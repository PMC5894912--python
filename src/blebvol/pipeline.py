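"""End-to-end measurement pipeline for phantoms.

Thin orchestration over the library modules: calibrate voxel pitches from an
en-face image of a ball of known diameter, auto-trace a phantom, count
pixels, and convert to μL.  Used by the CLI and by validation scripts; each
step is an ordinary library call and can be replaced piecemeal.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .calibration import (
    DiameterMeasurementSet,
    build_calibration,
    measure_diameter_px,
    project_en_face,
)
from .core_io import OCTVolume, VolumeMeasurement, VoxelCalibration
from .phantom import cap_height_for_volume, generate_ball_phantom, generate_bleb_phantom
from .segmentation import area_from_trace, double_semicircle, trace_phantom_boundaries
from .volumetry import total_volume

__all__ = [
    "calibrate_from_ball_volume",
    "measure_phantom",
    "phantom_recovery_errors",
]


def calibrate_from_ball_volume(
    ball_volume: OCTVolume,
    known_diameter_mm: float,
    projection: str = "max",
    medium_refractive_index: float = 1.336,
) -> VoxelCalibration:
    """Voxel calibration from one en-face view of a ball of known diameter."""
    enface = project_en_face(ball_volume, projection)
    dx = measure_diameter_px(enface, axis="x")
    dy = measure_diameter_px(enface, axis="y")
    with warnings.catch_warnings():
        # single automated measurement per axis: the zero-SD warning is expected
        warnings.simplefilter("ignore")
        return build_calibration(
            DiameterMeasurementSet(axis="x", diameters_px=[dx], known_diameter_mm=known_diameter_mm),
            DiameterMeasurementSet(axis="y", diameters_px=[dy], known_diameter_mm=known_diameter_mm),
            axial_range_air_mm=ball_volume.axial_range_air_mm,
            n_depth=ball_volume.n_depth,
            medium_refractive_index=medium_refractive_index,
        )


def measure_phantom(
    volume: OCTVolume,
    kind: str,
    cal: VoxelCalibration,
    double: bool | None = None,
) -> VolumeMeasurement:
    """Auto-trace a phantom and convert its pixel count to μL.

    ``double`` controls semicircle doubling; by default it is applied for
    balls (whose shadowed lower half is reconstructed by doubling) and not
    for blebs (fully visible).
    """
    if double is None:
        double = kind == "ball"
    trace = trace_phantom_boundaries(volume, truth_kind=kind)
    seg = area_from_trace(
        trace, (volume.n_bscans, volume.n_ascans, volume.n_depth), source="phantom_auto"
    )
    if double:
        seg = double_semicircle(seg)
    return total_volume(seg, cal, volume_id=volume.volume_id)


def phantom_recovery_errors(
    seeds: Sequence[int],
    ball_diameter_mm: float = 3.17,
    bleb_volumes_ul: Sequence[float] = (15.0, 30.0, 42.0),
    bleb_base_radii_mm: Sequence[float] = (2.2, 2.5, 2.764),
    volume_dims=(128, 1000, 512),
    scan_mm=(6.0, 6.0),
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Simulate, calibrate, trace and measure phantoms over several seeds.

    For each seed a shadowed ball of the given diameter is generated and used
    both as the calibration object and as a measurement target (with
    semicircle doubling); spherical-cap blebs of the requested volumes are
    then measured with the ball-derived calibration.  Returns one row per
    (seed, phantom) with the true and measured volume and the percent error.
    """
    rows = []
    for seed in seeds:
        ball, ball_truth = generate_ball_phantom(
            diameter_mm=ball_diameter_mm,
            volume_dims=volume_dims,
            scan_mm=scan_mm,
            shadowing=True,
            noise_sd=noise_sd,
            seed=int(seed),
        )
        cal = calibrate_from_ball_volume(ball, known_diameter_mm=ball_diameter_mm)
        meas = measure_phantom(ball, "ball", cal)
        rows.append(
            {
                "seed": int(seed),
                "kind": "ball",
                "true_ul": ball_truth.true_volume_ul,
                "measured_ul": meas.volume_ul,
            }
        )
        for target_ul, base_r in zip(bleb_volumes_ul, bleb_base_radii_mm):
            h = cap_height_for_volume(base_r, target_ul)
            bleb, truth = generate_bleb_phantom(
                cap_base_radius_mm=base_r,
                cap_height_mm=h,
                volume_dims=volume_dims,
                scan_mm=scan_mm,
                noise_sd=noise_sd,
                seed=int(seed) + 7919,  # decouple bleb noise from the ball's
            )
            meas = measure_phantom(bleb, "bleb", cal)
            rows.append(
                {
                    "seed": int(seed),
                    "kind": f"bleb_{target_ul:g}ul",
                    "true_ul": truth.true_volume_ul,
                    "measured_ul": meas.volume_ul,
                }
            )
    df = pd.DataFrame(rows)
    df["pct_error"] = (df["measured_ul"] - df["true_ul"]).abs() / df["true_ul"] * 100.0
    return df
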