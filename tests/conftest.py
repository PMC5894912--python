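"""Shared fixtures: reduced-size phantoms reused across test modules.

Unit tests run at 64×300×256 (or similar) grids to stay fast; the full
128×1000×512 acquisition geometry is exercised in test_acceptance.py.
"""

import numpy as np
import pytest

from blebvol import core_io, phantom

SMALL_DIMS = (64, 300, 256)


@pytest.fixture(scope="session")
def ball_small():
    """Shadowed 3.17 mm ball phantom at reduced grid, noise SD 0.05."""
    vol, truth = phantom.generate_ball_phantom(
        diameter_mm=3.17, volume_dims=SMALL_DIMS, scan_mm=(6.0, 6.0),
        shadowing=True, noise_sd=0.05, seed=11,
    )
    return vol, truth


@pytest.fixture(scope="session")
def bleb_small():
    """~30 μL spherical-cap bleb phantom at reduced grid, noise SD 0.05."""
    h = phantom.cap_height_for_volume(2.5, 30.0)
    vol, truth = phantom.generate_bleb_phantom(
        cap_base_radius_mm=2.5, cap_height_mm=h, volume_dims=SMALL_DIMS,
        scan_mm=(6.0, 6.0), noise_sd=0.05, seed=12,
    )
    return vol, truth


@pytest.fixture
def tiny_volume():
    """A 16×20×12 deterministic volume for I/O round trips."""
    rng = np.random.default_rng(5)
    arr = rng.random((16, 20, 12)).astype(np.float32)
    return core_io.OCTVolume(
        intensities=arr, nominal_scan_x_mm=6.0, nominal_scan_y_mm=6.0,
        scan_angle_deg=0.0, axial_range_air_mm=7.4, volume_id="tiny",
    )
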