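"""Synthetic OCT phantoms with analytically known volumes.

Real intraoperative validation used (a) a ceramic ball of known diameter
resting on the retina and (b) subretinal blebs of injected fluid.  Neither
can ship with a software package, so this module renders both as synthetic
OCT volumes whose true volumes are closed-form:

* **ball** — a sphere of diameter *d* tangent to a flat retinal surface,
  V = (π/6)·d³.  Only the top surface reflects; everything beneath it within
  the ball's lateral footprint is shadowed, exactly as a highly reflective
  ball appears on OCT (the lower half is invisible).
* **bleb** — a spherical cap of base radius *a* and height *h* resting on a
  bright RPE plane, with a neurosensory-retina layer draped over the dome.
  With sphere radius R = (a² + h²)/(2h), V = π·h²·(3R − h)/3.

Optional realism hooks: an air bubble occupying the top of the bleb (marked
by a hyperreflective line at the retina–air interface, as an unrecognized
bubble appears in practice) and leakage particles scattered in the vitreous
above the retina, annotated in ground truth by the volume fraction they
represent.

Geometry is rasterized by voxel-centre membership: a voxel belongs to a shape
iff its centre lies inside the analytic surface, which is unbiased as the
pitch shrinks and lets tests compare voxel counts against the closed forms.
Noise is additive Gaussian on intensity, clipped to [0, 1]; OCT speckle
statistics are deliberately not modelled — the measurement method is purely
geometric, and noise exists only to stress segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np
from scipy.optimize import brentq

from .core_io import OCTVolume
from .exceptions import GeometryError

__all__ = [
    "PhantomGroundTruth",
    "sphere_volume_ul",
    "spherical_cap_volume_ul",
    "cap_height_for_volume",
    "generate_ball_phantom",
    "generate_bleb_phantom",
    "BACKGROUND",
    "RETINA_BED",
    "BALL_SURFACE",
    "RETINA_LAYER",
    "RPE_PLANE",
    "BLEB_FLUID",
    "AIR_INTERFACE",
    "LEAK_PARTICLE",
]

# rendering intensities (arbitrary reflectivity units in [0, 1])
BACKGROUND = 0.0      # vitreous / unfilled space
RETINA_BED = 0.2      # flat retinal surface the ball rests on (kept dim so the
                      # en-face ball disc is the single dominant blob)
BALL_SURFACE = 0.95   # reflective top surface of the ceramic ball
RETINA_LAYER = 0.85   # neurosensory retina draped over the bleb
RPE_PLANE = 0.9       # retinal pigment epithelium
BLEB_FLUID = 0.05     # hypo-reflective injected fluid
AIR_INTERFACE = 1.0   # hyperreflective retina–air interface line
LEAK_PARTICLE = 0.9   # triamcinolone particles leaked into the vitreous

_RETINA_BED_THICKNESS_MM = 0.3
_RPE_THICKNESS_MM = 0.15
_DEFAULT_STRUCTURE_DEPTH_FRAC = 0.75


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Generative parameters and the analytic true volume of a phantom.

    ``true_volume_ul`` is the closed-form volume of the generative shape
    (1 mm³ = 1 μL); for blebs it includes any air bubble, whose own volume is
    recorded separately (the bubble is part of the bleb, not of the fluid).
    """

    kind: str                      # "ball" | "bleb"
    true_volume_ul: float
    diameter_mm: float | None = None
    cap_base_radius_mm: float | None = None
    cap_height_mm: float | None = None
    air_bubble_volume_ul: float = 0.0
    leakage_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ball", "bleb"):
            raise GeometryError(f"unknown phantom kind {self.kind!r}")
        if self.air_bubble_volume_ul > self.true_volume_ul + 1e-12:
            raise GeometryError("air bubble cannot exceed the bleb volume")
        if not 0.0 <= self.leakage_fraction <= 1.0:
            raise GeometryError("leakage_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def sphere_volume_ul(diameter_mm: float) -> float:
    """Volume of a sphere, (π/6)·d³, in μL for d in mm."""
    if diameter_mm <= 0:
        raise GeometryError("diameter must be > 0")
    return math.pi / 6.0 * diameter_mm ** 3


def spherical_cap_volume_ul(base_radius_mm: float, height_mm: float) -> float:
    """Volume of a spherical cap with base radius a and height h.

    The cap sits on a sphere of radius R = (a² + h²)/(2h); its volume is
    π·h²·(3R − h)/3.  h → 0 at fixed a gives 0.
    """
    if base_radius_mm <= 0:
        raise GeometryError("cap base radius must be > 0")
    if height_mm < 0:
        raise GeometryError("cap height must be >= 0")
    if height_mm == 0.0:
        return 0.0
    a, h = base_radius_mm, height_mm
    big_r = (a * a + h * h) / (2.0 * h)
    if h > 2.0 * big_r + 1e-12:
        raise GeometryError("cap height exceeds sphere diameter")
    return math.pi * h * h * (3.0 * big_r - h) / 3.0


def cap_height_for_volume(base_radius_mm: float, volume_ul: float) -> float:
    """Invert the cap volume for h at fixed base radius (numeric, monotone)."""
    if volume_ul <= 0:
        raise GeometryError("target volume must be > 0")
    # at h = a the cap is a hemisphere; beyond h = a the base is no longer the
    # widest section, but the formula stays valid up to a full sphere of
    # radius a (h = 2a is only reachable when a is the sphere radius).
    h_hi = 2.0 * base_radius_mm
    f = lambda h: spherical_cap_volume_ul(base_radius_mm, h) - volume_ul
    if f(h_hi) < 0:
        raise GeometryError("target volume too large for this base radius")
    return float(brentq(f, 1e-9, h_hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# shared rendering helpers
# ---------------------------------------------------------------------------

def _pitches(volume_dims, scan_mm, axial_range_air_mm, medium_refractive_index):
    n_b, n_a, n_z = volume_dims
    scan_x, scan_y = scan_mm
    xp = scan_x / n_a
    yp = scan_y / n_b
    zp = axial_range_air_mm / n_z / medium_refractive_index
    return xp, yp, zp


def _lateral_grids(n_b, n_a, xp, yp):
    y = (np.arange(n_b, dtype=np.float32) + 0.5) * np.float32(yp)
    x = (np.arange(n_a, dtype=np.float32) + 0.5) * np.float32(xp)
    return y[:, None], x[None, :]


def _depth_index_at_or_below(z_mm, zp):
    """Index of the first voxel whose centre depth is >= z_mm."""
    return np.ceil(z_mm / zp - 0.5).astype(np.int64)


def _finish(arr, noise_sd, rng):
    if noise_sd > 0:
        noise = rng.standard_normal(size=arr.shape, dtype=np.float32)
        noise *= np.float32(noise_sd)
        arr += noise
    np.clip(arr, 0.0, 1.0, out=arr)
    return arr


def _maybe_rotate(arr, scan_mm, scan_angle_deg):
    """A 90° scan swaps the fast (A-scan) and slow (B-scan) axes."""
    if scan_angle_deg not in (0, 90):
        raise GeometryError("scan_angle_deg must be 0 or 90")
    if scan_angle_deg == 90:
        return np.ascontiguousarray(np.swapaxes(arr, 0, 1)), (scan_mm[1], scan_mm[0])
    return arr, scan_mm


# ---------------------------------------------------------------------------
# ball phantom
# ---------------------------------------------------------------------------

def generate_ball_phantom(
    diameter_mm: float = 3.17,
    volume_dims: Tuple[int, int, int] = (128, 1000, 512),
    scan_mm: Tuple[float, float] = (6.0, 6.0),
    shadowing: bool = True,
    noise_sd: float = 0.05,
    seed: int = 0,
    scan_angle_deg: float = 0.0,
    axial_range_air_mm: float = 7.4,
    medium_refractive_index: float = 1.336,
    surface_depth_frac: float = _DEFAULT_STRUCTURE_DEPTH_FRAC,
    volume_id: str = "",
) -> Tuple[OCTVolume, PhantomGroundTruth]:
    """Render a reflective ball of known diameter resting on a retinal surface.

    ``volume_dims`` is (n_bscans, n_ascans, n_depth) at scan angle 0; with
    ``scan_angle_deg=90`` the lateral axes (and their nominal scan lengths)
    are swapped, modelling the same object scanned with the fast axis rotated.
    When ``shadowing`` is on, every voxel strictly below the ball's top
    surface within its lateral footprint is exact background — only the top
    hemisphere is visible, as for a real opaque ball.
    """
    n_b, n_a, n_z = volume_dims
    xp, yp, zp = _pitches(volume_dims, scan_mm, axial_range_air_mm, medium_refractive_index)
    rad = diameter_mm / 2.0
    if diameter_mm > min(scan_mm):
        raise GeometryError(
            f"ball diameter {diameter_mm} mm exceeds the scan field {scan_mm} mm"
        )
    z_retina = surface_depth_frac * n_z * zp     # depth of the retinal surface
    z_center = z_retina - rad                    # ball tangent to the surface
    if z_center - rad < 0:
        raise GeometryError("ball does not fit above the retinal surface in depth")

    rng = np.random.default_rng(seed)
    arr = np.zeros((n_b, n_a, n_z), dtype=np.float32)

    # retinal bed
    k0 = int(_depth_index_at_or_below(z_retina, zp))
    k1 = int(_depth_index_at_or_below(z_retina + _RETINA_BED_THICKNESS_MM, zp))
    arr[:, :, max(k0, 0):min(k1, n_z)] = RETINA_BED

    # top-surface shell: one voxel per footprint column
    yy, xx = _lateral_grids(n_b, n_a, xp, yp)
    cy, cx = scan_mm[1] / 2.0, scan_mm[0] / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    inside = r2 <= rad * rad
    bb, aa = np.nonzero(inside)
    z_surf = z_center - np.sqrt(np.maximum(rad * rad - r2[bb, aa], 0.0))
    k_top = np.clip(_depth_index_at_or_below(z_surf, zp), 0, n_z - 1)
    arr[bb, aa, k_top] = BALL_SURFACE

    arr = _finish(arr, noise_sd, rng)

    if shadowing:
        sub = arr[bb, aa, :]
        karr = np.arange(n_z, dtype=np.int64)[None, :]
        sub[karr > k_top[:, None]] = BACKGROUND
        arr[bb, aa, :] = sub

    arr, scan_out = _maybe_rotate(arr, scan_mm, scan_angle_deg)
    vol = OCTVolume(
        intensities=arr,
        nominal_scan_x_mm=scan_out[0],
        nominal_scan_y_mm=scan_out[1],
        scan_angle_deg=scan_angle_deg,
        axial_range_air_mm=axial_range_air_mm,
        volume_id=volume_id or f"ball-d{diameter_mm}-s{seed}",
    )
    truth = PhantomGroundTruth(
        kind="ball",
        true_volume_ul=sphere_volume_ul(diameter_mm),
        diameter_mm=diameter_mm,
        noise_sd=noise_sd,
        seed=seed,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# bleb phantom
# ---------------------------------------------------------------------------

def generate_bleb_phantom(
    cap_base_radius_mm: float,
    cap_height_mm: float,
    retina_thickness_mm: float = 0.2,
    volume_dims: Tuple[int, int, int] = (128, 1000, 512),
    scan_mm: Tuple[float, float] = (6.0, 6.0),
    air_bubble_volume_ul: float = 0.0,
    leakage_fraction: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    scan_angle_deg: float = 0.0,
    axial_range_air_mm: float = 7.4,
    medium_refractive_index: float = 1.336,
    rpe_depth_frac: float = _DEFAULT_STRUCTURE_DEPTH_FRAC,
    volume_id: str = "",
) -> Tuple[OCTVolume, PhantomGroundTruth]:
    """Render a dome-shaped subretinal bleb on a flat RPE plane.

    The bleb is a spherical cap of hypo-reflective fluid between the bright
    RPE plane below and the bright neurosensory-retina layer draped over the
    dome above.  Outside the cap footprint the retina lies directly on the
    RPE.  ``air_bubble_volume_ul`` > 0 places an air pocket at the top of the
    bleb, marked by a hyperreflective line at the retina–air interface;
    ``leakage_fraction`` > 0 scatters bright particles in the vitreous above
    the retina and records the fraction of injected volume they represent.
    """
    if cap_height_mm <= 0:
        raise GeometryError("cap_height_mm must be > 0")
    if cap_base_radius_mm <= 0:
        raise GeometryError("cap_base_radius_mm must be > 0")
    n_b, n_a, n_z = volume_dims
    xp, yp, zp = _pitches(volume_dims, scan_mm, axial_range_air_mm, medium_refractive_index)
    a, h = cap_base_radius_mm, cap_height_mm
    true_vol = spherical_cap_volume_ul(a, h)
    if air_bubble_volume_ul < 0:
        raise GeometryError("air_bubble_volume_ul must be >= 0")
    if air_bubble_volume_ul > true_vol:
        raise GeometryError(
            f"air bubble ({air_bubble_volume_ul} μL) larger than the cap ({true_vol:.3g} μL)"
        )
    if 2.0 * a > min(scan_mm):
        raise GeometryError("cap base does not fit in the lateral scan field")
    big_r = (a * a + h * h) / (2.0 * h)
    z_rpe = rpe_depth_frac * n_z * zp
    if h + retina_thickness_mm > z_rpe:
        raise GeometryError("cap plus retina does not fit above the RPE in depth")

    rng = np.random.default_rng(seed)

    yy, xx = _lateral_grids(n_b, n_a, xp, yp)
    cy, cx = scan_mm[1] / 2.0, scan_mm[0] / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2                     # (n_b, n_a)
    z_center = z_rpe + (big_r - h)                           # sphere centre depth
    z_surf = np.full((n_b, n_a), z_rpe, dtype=np.float64)    # cap surface depth
    in_cap = r2 <= a * a
    z_surf[in_cap] = z_center - np.sqrt(big_r * big_r - r2[in_cap])

    # per-column layer boundaries as depth indices (voxel k spans centre
    # depth (k + 0.5)·zp; a region [z0, z1) in depth covers k in
    # [ceil(z0/zp - 0.5), ceil(z1/zp - 0.5)) — the voxel-centre rule)
    k_surf = np.clip(_depth_index_at_or_below(z_surf, zp), 0, n_z)
    k_ret_top = np.clip(_depth_index_at_or_below(z_surf - retina_thickness_mm, zp), 0, n_z)
    k_rpe0 = int(np.clip(_depth_index_at_or_below(z_rpe, zp), 0, n_z))
    k_rpe1 = int(np.clip(_depth_index_at_or_below(z_rpe + _RPE_THICKNESS_MM, zp), 0, n_z))

    # piecewise-constant per-column profiles built as a difference image and
    # integrated with one cumulative sum along depth — regions are disjoint
    diff = np.zeros((n_b, n_a, n_z + 1), dtype=np.float32)
    rows = np.arange(n_b)[:, None]
    cols = np.arange(n_a)[None, :]

    # neurosensory retina draped over the dome (and flat on the RPE outside)
    diff[rows, cols, k_ret_top] += RETINA_LAYER
    diff[rows, cols, k_surf] -= RETINA_LAYER

    in_bubble = np.zeros_like(in_cap)
    k_air = np.full((n_b, n_a), k_rpe0, dtype=np.int64)
    if air_bubble_volume_ul > 0:
        # the bubble is a smaller cap of the SAME sphere (radius R), of
        # height h_b <= h, occupying the top of the bleb down to a flat
        # air–fluid interface
        sub_cap = lambda hb: math.pi * hb * hb * (3.0 * big_r - hb) / 3.0
        bubble_h = float(brentq(lambda hb: sub_cap(hb) - air_bubble_volume_ul, 0.0, h, xtol=1e-12))
        z_air = (z_rpe - h) + bubble_h                        # air–fluid plane depth
        in_bubble = in_cap & (z_surf < z_air)
        k_air = np.clip(_depth_index_at_or_below(np.full_like(z_surf, z_air), zp), 0, n_z)

    # bleb fluid between the cap surface (or the air–fluid plane) and the RPE
    bb, aa = np.nonzero(in_cap & ~in_bubble)
    diff[bb, aa, k_surf[bb, aa]] += BLEB_FLUID
    diff[bb, aa, k_rpe0] -= BLEB_FLUID
    if in_bubble.any():
        bb, aa = np.nonzero(in_bubble)
        # hyperreflective line at the retina–air interface (top of the bubble)
        k_line_end = np.minimum(k_surf[bb, aa] + 2, k_rpe0)
        diff[bb, aa, k_surf[bb, aa]] += AIR_INTERFACE
        diff[bb, aa, k_line_end] -= AIR_INTERFACE
        # air below the line is signal-poor (background); fluid resumes below
        k_fluid_top = np.maximum(k_air[bb, aa], k_line_end)
        diff[bb, aa, k_fluid_top] += BLEB_FLUID
        diff[bb, aa, k_rpe0] -= BLEB_FLUID

    np.cumsum(diff, axis=2, out=diff)
    arr = np.ascontiguousarray(diff[:, :, :n_z])
    del diff
    # RPE plane everywhere
    arr[:, :, k_rpe0:k_rpe1] = RPE_PLANE

    # optional leakage particles in the vitreous above the retina
    if leakage_fraction > 0:
        z_top_structure = float(z_surf.min()) - retina_thickness_mm
        k_ceiling = max(int(_depth_index_at_or_below(z_top_structure, zp)) - 4, 4)
        n_particles = max(1, int(round(leakage_fraction * 300)))
        pb = rng.integers(0, n_b - 1, size=n_particles)
        pa = rng.integers(0, n_a - 2, size=n_particles)
        pk = rng.integers(0, k_ceiling, size=n_particles)
        for db in (0, 1):
            for da in (0, 1, 2):
                for dk in (0, 1):
                    arr[np.minimum(pb + db, n_b - 1),
                        np.minimum(pa + da, n_a - 1),
                        np.minimum(pk + dk, n_z - 1)] = LEAK_PARTICLE

    arr = _finish(arr, noise_sd, rng)
    arr, scan_out = _maybe_rotate(arr, scan_mm, scan_angle_deg)
    vol = OCTVolume(
        intensities=arr,
        nominal_scan_x_mm=scan_out[0],
        nominal_scan_y_mm=scan_out[1],
        scan_angle_deg=scan_angle_deg,
        axial_range_air_mm=axial_range_air_mm,
        volume_id=volume_id or f"bleb-a{cap_base_radius_mm}-h{cap_height_mm}-s{seed}",
    )
    truth = PhantomGroundTruth(
        kind="bleb",
        true_volume_ul=true_vol,
        cap_base_radius_mm=cap_base_radius_mm,
        cap_height_mm=cap_height_mm,
        air_bubble_volume_ul=air_bubble_volume_ul,
        leakage_fraction=leakage_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
    return vol, truth
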