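"""Pupil-plane optics: modulated pupil fields and scalar-diffraction PSFs.

The imaging system is modelled by its complex pupil function sampled on the
transverse spatial-frequency grid of the image.  Amplitude modulation
(annular masks, 4x4 gated grids) and phase modulation (Zernike aberrations)
are applied inside the numerical-aperture cutoff ``rho_c = NA / lambda``.
A 3D intensity PSF follows by scalar angular-spectrum propagation: each
defocus plane is the squared modulus of the inverse Fourier transform of
the pupil multiplied by ``exp(i 2 pi z k_z)`` with
``k_z = sqrt((n/lambda)^2 - k_x^2 - k_y^2)`` on the pupil support.

This is a scalar, aberration-by-design model for diffraction-limited
wide-field systems; no vectorial (Richards-Wolf) or index-mismatch
(Gibson-Lanni) corrections are applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .errors import EmptyApertureError, ValidationError
from .stacks import PSFStack

__all__ = [
    "OpticalConfig",
    "ApertureModulation",
    "AberrationSpec",
    "PupilField",
    "make_pupil",
    "zernike_phase",
    "noll_to_nm",
    "psf_from_pupil",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and sampling parameters of the simulated microscope.

    Parameters
    ----------
    na:
        Numerical aperture (dimensionless, ``0 < na <= refractive_index``).
    wavelength_nm:
        Emission wavelength in nm.
    voxel_xy_nm, voxel_z_nm:
        Lateral / axial sampling in nm.
    nx, ny, nz:
        Grid size in voxels.
    refractive_index:
        Immersion-medium refractive index (default 1.0, air objective).
    """

    na: float
    wavelength_nm: float
    voxel_xy_nm: float
    voxel_z_nm: float
    nx: int
    ny: int
    nz: int
    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.na > 0:
            raise ValidationError("numerical aperture must be positive")
        if self.na > self.refractive_index:
            raise ValidationError(
                f"NA ({self.na}) cannot exceed the medium index "
                f"({self.refractive_index})"
            )
        if not (self.wavelength_nm > 0 and self.voxel_xy_nm > 0 and self.voxel_z_nm > 0):
            raise ValidationError("wavelength and voxel sizes must be positive")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValidationError("grid dimensions must be >= 1")
        nyquist = self.wavelength_nm / (4.0 * self.na)
        if self.voxel_xy_nm > nyquist:
            warnings.warn(
                f"lateral sampling {self.voxel_xy_nm} nm exceeds the incoherent "
                f"Nyquist interval lambda/(4 NA) = {nyquist:.1f} nm",
                UserWarning,
                stacklevel=2,
            )

    @property
    def cutoff(self) -> float:
        """Pupil cutoff radius NA/lambda in cycles/nm."""
        return self.na / self.wavelength_nm

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    def frequency_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(ky, kx) meshgrids in cycles/nm, FFT (unshifted) order."""
        kx = sfft.fftfreq(self.nx, d=self.voxel_xy_nm)
        ky = sfft.fftfreq(self.ny, d=self.voxel_xy_nm)
        return np.meshgrid(ky, kx, indexing="ij")


@dataclass(frozen=True)
class ApertureModulation:
    """Amplitude modulation applied to the equivalent pupil.

    ``mode`` is one of ``open`` (clear disc), ``annular`` (ring with
    inner/outer diameter ratio ``obstruction_ratio``) or ``grid`` (the
    pupil's bounding square split into a 4x4 grid whose cells are gated
    open/closed, emulating random amplitude modulation).  In ``grid`` mode
    either supply ``grid_mask`` (4x4 boolean, True = open) or a
    ``grid_seed`` from which a Bernoulli(0.5) mask is drawn, re-drawn until
    at least one cell that overlaps the disc is open.
    """

    mode: str = "open"
    obstruction_ratio: float = 0.0
    grid_mask: np.ndarray | None = None
    grid_seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("open", "annular", "grid"):
            raise ValidationError(f"unknown aperture mode {self.mode!r}")
        if self.mode == "annular" and not 0.0 <= self.obstruction_ratio < 1.0:
            raise ValidationError("obstruction_ratio must lie in [0, 1)")
        if self.mode == "grid":
            if self.grid_mask is not None:
                mask = np.asarray(self.grid_mask, dtype=bool)
                if mask.shape != (4, 4):
                    raise ValidationError("grid_mask must be 4x4")
                if not mask.any():
                    raise EmptyApertureError("grid_mask gates every cell closed")
                object.__setattr__(self, "grid_mask", mask)
            elif self.grid_seed is None:
                raise ValidationError("grid mode needs grid_mask or grid_seed")

    def resolve_mask(self) -> np.ndarray:
        """The concrete 4x4 gate matrix (drawing from grid_seed if needed)."""
        if self.grid_mask is not None:
            return self.grid_mask
        rng = np.random.default_rng(self.grid_seed)
        while True:
            mask = rng.random((4, 4)) < 0.5
            if mask.any():
                return mask


@dataclass(frozen=True)
class AberrationSpec:
    """Phase aberration as Zernike terms: list of (Noll index, radians RMS)."""

    zernike_terms: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        terms = tuple((int(j), float(c)) for j, c in self.zernike_terms)
        for j, _ in terms:
            if j < 1:
                raise ValidationError(f"Noll index must be >= 1; got {j}")
        object.__setattr__(self, "zernike_terms", terms)


@dataclass
class PupilField:
    """Complex pupil amplitude on the image's spatial-frequency grid.

    ``field`` is stored in FFT (unshifted) frequency order so that an
    inverse 2D FFT directly yields the coherent amplitude spread function.
    """

    field: np.ndarray
    config: OpticalConfig
    support: np.ndarray  # boolean: inside-cutoff AND amplitude-open

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.field)):
            raise ValidationError("pupil field must be finite")


# ---------------------------------------------------------------------------
# Zernike phase
# ---------------------------------------------------------------------------


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll index (1-based) to radial degree n and azimuthal order m."""
    if j < 1:
        raise ValidationError(f"Noll index must be >= 1; got {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out += coeff * rho ** (n - 2 * k)
    return out


def zernike_phase(
    aberration: AberrationSpec, rho: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Sum of RMS-normalised Zernike polynomials on the unit pupil disc.

    ``rho`` is the pupil radius normalised to the cutoff (so the aberration
    lives on the unit disc) and ``theta`` the azimuth.  With the Noll
    normalisation a unit coefficient has unit RMS phase over the disc.
    Values at ``rho > 1`` are computed but are meant to be masked by the
    pupil support.
    """

    phase = np.zeros_like(rho, dtype=np.float64)
    for j, coeff in aberration.zernike_terms:
        n, m = noll_to_nm(j)
        radial = _zernike_radial(n, abs(m), rho)
        norm = math.sqrt(n + 1.0) if m == 0 else math.sqrt(2.0 * (n + 1.0))
        if m > 0:
            term = norm * radial * np.cos(m * theta)
        elif m < 0:
            term = norm * radial * np.sin(-m * theta)
        else:
            term = norm * radial
        phase += coeff * term
    return phase


# ---------------------------------------------------------------------------
# pupil construction and propagation
# ---------------------------------------------------------------------------


def make_pupil(
    config: OpticalConfig,
    modulation: ApertureModulation | None = None,
    aberration: AberrationSpec | None = None,
) -> PupilField:
    """Build the complex pupil under the given amplitude/phase modulation.

    The amplitude is the aperture indicator (disc, annulus, or 4x4 gated
    disc) and the phase is the Zernike sum; everything is strictly zero
    outside the cutoff radius.
    """

    modulation = modulation or ApertureModulation()
    aberration = aberration or AberrationSpec()
    ky, kx = config.frequency_grid()
    rho_c = config.cutoff
    kr = np.hypot(ky, kx)
    disc = kr <= rho_c

    if modulation.mode == "open":
        amp = disc
    elif modulation.mode == "annular":
        amp = disc & (kr > modulation.obstruction_ratio * rho_c)
    else:  # grid
        mask = modulation.resolve_mask()
        # cell indices over the bounding square [-rho_c, rho_c]^2
        col = np.clip(np.floor((kx + rho_c) / (2 * rho_c / 4)), 0, 3).astype(int)
        row = np.clip(np.floor((ky + rho_c) / (2 * rho_c / 4)), 0, 3).astype(int)
        amp = disc & mask[row, col]

    if not amp.any():
        raise EmptyApertureError("aperture modulation blocks the entire pupil")

    rho = np.divide(kr, rho_c)
    theta = np.arctan2(ky, kx)
    phase = zernike_phase(aberration, rho, theta)
    field = np.where(amp, np.exp(1j * phase), 0.0 + 0.0j)
    return PupilField(field=field, config=config, support=amp)


def psf_from_pupil(
    pupil: PupilField, config: OpticalConfig | None = None, *, normalize: bool = True
) -> PSFStack:
    """Propagate a pupil to a 3D intensity PSF by the angular spectrum.

    Plane ``iz`` sits at defocus ``z = (iz - nz//2) * voxel_z_nm`` so the
    focal plane is the stack's centre slice and, for a real centrosymmetric
    pupil, the stack is mirror-symmetric in z.  The intensity PSF is
    returned normalised to unit sum over the finite stack unless
    ``normalize=False`` (raw squared-modulus values, used for energy
    bookkeeping).
    """

    config = config or pupil.config
    if pupil.field.shape != (config.ny, config.nx):
        raise ValidationError("pupil and config grids disagree")
    ky, kx = config.frequency_grid()
    n_over_lambda = config.refractive_index / config.wavelength_nm
    kz_sq = n_over_lambda**2 - ky**2 - kx**2
    kz = np.sqrt(np.clip(kz_sq, 0.0, None))

    out = np.empty(config.shape, dtype=np.float64)
    cz = config.nz // 2
    for iz in range(config.nz):
        z = (iz - cz) * config.voxel_z_nm
        defocused = pupil.field * np.exp(2j * np.pi * z * kz)
        amp = sfft.ifft2(defocused)
        out[iz] = sfft.fftshift(np.abs(amp) ** 2)

    stack = PSFStack(
        data=out,
        voxel_xy_nm=config.voxel_xy_nm,
        voxel_z_nm=config.voxel_z_nm,
        normalized=False,
    )
    return stack.normalized_copy() if normalize else stack
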