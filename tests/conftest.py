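"""Shared fixtures: a scaled-down optical bench reused across the suite.

Everything is generated programmatically; session scope keeps the cost of
the pupil propagations and phantoms to one computation each.
"""

import numpy as np
import pytest

from psfdecouple import (
    ApertureModulation,
    OpticalConfig,
    PhantomSpec,
    generate_phantom,
    make_pupil,
    psf_from_pupil,
)

VOXEL_NM = 325.0


@pytest.fixture(scope="session")
def optics64():
    """NA 0.75, 570 nm emission, 325 nm voxels on a 64x64x32 grid."""
    return OpticalConfig(
        na=0.75, wavelength_nm=570.0, voxel_xy_nm=VOXEL_NM, voxel_z_nm=VOXEL_NM,
        nx=64, ny=64, nz=32,
    )


@pytest.fixture(scope="session")
def h_open(optics64):
    """Wide-field (clear pupil) PSF."""
    return psf_from_pupil(make_pupil(optics64))


@pytest.fixture(scope="session")
def h_annular(optics64):
    """Annular-aperture PSF, obstruction ratio 0.8."""
    mod = ApertureModulation("annular", obstruction_ratio=0.8)
    return psf_from_pupil(make_pupil(optics64, mod))


@pytest.fixture(scope="session")
def h_grid(optics64):
    """Randomly 4x4-gated pupil PSF (seeded)."""
    return psf_from_pupil(make_pupil(optics64, ApertureModulation("grid", grid_seed=5)))


@pytest.fixture(scope="session")
def phantom64():
    """Spheres+rods modulator phantom on the 64x64x32 grid."""
    return generate_phantom(PhantomSpec.for_shape((32, 64, 64), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
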