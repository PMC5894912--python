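"""The core volume arithmetic.

Voxel volume = X pitch × Y pitch × Z pitch (mm³ = μL per voxel).
Total volume = voxel volume × total number of segmented pixels across all
B-scans.  Measured volumes are compared against the intended injected dose
by absolute difference and percent error, with percent error signed so that
a shortfall (measured < intended — a volume loss) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import math

import pandas as pd

from .core_io import VolumeMeasurement, VoxelCalibration
from .exceptions import InvariantError
from .phantom import sphere_volume_ul
from .segmentation import SegmentationResult
from .uncertainty import UncertaintyBudget

__all__ = [
    "DoseComparison",
    "voxel_volume_ul",
    "total_volume",
    "compare_to_intended",
    "sphere_volume_from_diameter",
    "dose_table",
]


@dataclass(frozen=True)
class DoseComparison:
    """Measured bleb volume against the intended injected dose.

    ``percent_error`` and ``measured_loss_pct`` are both
    (intended − measured)/intended × 100: positive when fluid was lost.
    ``surgeon_loss_pct`` is the surgeon's estimate of the same loss, when
    recorded, for agreement analysis.
    """

    intended_ul: float
    measured_ul: float
    abs_difference_ul: float
    percent_error: float
    measured_loss_pct: float
    surgeon_loss_pct: Optional[float] = None
    volume_id: str = ""

    def __post_init__(self) -> None:
        if abs(self.abs_difference_ul - abs(self.intended_ul - self.measured_ul)) > 1e-9:
            raise InvariantError("abs_difference_ul must equal |intended - measured|")


def voxel_volume_ul(cal: VoxelCalibration) -> float:
    """Volume of one voxel, the product of the three pitches (mm³ = μL)."""
    return cal.x_pitch_mm * cal.y_pitch_mm * cal.z_pitch_mm


def total_volume(
    seg: SegmentationResult,
    cal: VoxelCalibration,
    volume_id: str = "",
    budget: UncertaintyBudget | None = None,
) -> VolumeMeasurement:
    """Total volume = voxel volume × total segmented pixel count.

    If an :class:`~blebvol.uncertainty.UncertaintyBudget` is supplied its
    relative SD scales the measured volume into the absolute uncertainty;
    otherwise both uncertainty fields are 0.
    """
    vol = voxel_volume_ul(cal) * seg.total_pixels
    if budget is not None:
        rel = budget.rel_sd_total
        abs_u = rel * vol
    else:
        rel, abs_u = 0.0, 0.0
    return VolumeMeasurement(
        volume_ul=vol,
        total_pixels=seg.total_pixels,
        abs_uncertainty_ul=abs_u,
        rel_uncertainty_pct=rel * 100.0,
        calibration_source=cal.source,
        volume_id=volume_id,
    )


def compare_to_intended(
    measured: VolumeMeasurement | float,
    intended_ul: float,
    surgeon_loss_pct: float | None = None,
) -> DoseComparison:
    """Absolute difference and percent error of a measured volume vs the dose.

    Accepts a :class:`VolumeMeasurement` or a bare volume in μL.
    """
    if intended_ul <= 0:
        raise InvariantError("intended volume must be > 0")
    if isinstance(measured, VolumeMeasurement):
        m, vid = measured.volume_ul, measured.volume_id
    else:
        m, vid = float(measured), ""
    loss_pct = (intended_ul - m) / intended_ul * 100.0
    return DoseComparison(
        intended_ul=intended_ul,
        measured_ul=m,
        abs_difference_ul=abs(intended_ul - m),
        percent_error=loss_pct,
        measured_loss_pct=loss_pct,
        surgeon_loss_pct=surgeon_loss_pct,
        volume_id=vid,
    )


def sphere_volume_from_diameter(d_mm: float) -> float:
    """(π/6)·d³ in μL — e.g. a 3.17 mm calibration ball holds 16.7 μL."""
    return sphere_volume_ul(d_mm)


def dose_table(comparisons: Iterable[DoseComparison]) -> pd.DataFrame:
    """Tidy per-bleb table: id, measured μL, difference μL, percent error."""
    rows = [
        {
            "bleb_id": c.volume_id,
            "measured_ul": c.measured_ul,
            "intended_ul": c.intended_ul,
            "abs_difference_ul": c.abs_difference_ul,
            "percent_error": c.percent_error,
            "surgeon_loss_pct": c.surgeon_loss_pct if c.surgeon_loss_pct is not None else math.nan,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)
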