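"""Synthetic fluorescent volumes: spheres+rods phantoms and bead fields.

Two generators cover the simulation study:

* :func:`generate_phantom` builds the modulator sample — a sparse volume of
  solid spheres and capsule-shaped rods at random positions, orientations
  and intensities.  Such a structured, bright object is what makes the
  sample-prior PSF decoupling well posed.
* :func:`generate_bead_field` builds a field of sub-diffraction (default
  500 nm) fluorescent microspheres, the classical target for direct PSF
  measurement, together with the ground-truth bead centres.

Voxel membership is decided by voxel-centre inclusion (no partial-volume
antialiasing), which keeps object counts and analytic volumes exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PlacementError, ValidationError
from .stacks import VolumeStack

__all__ = ["PhantomSpec", "BeadFieldSpec", "generate_phantom", "generate_bead_field"]

_MAX_TRIES = 200  # rejection-sampling attempts per object


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the spheres+rods modulator phantom.

    Shapes are ``(nz, ny, nx)``; all lengths in nm.  Objects are placed
    uniformly at random inside the volume shrunk by ``margin`` voxels and,
    when ``allow_overlap`` is false, re-drawn until they do not touch a
    previously placed object (bounded retries).
    """

    shape: tuple[int, int, int] = (128, 256, 256)
    voxel_xy_nm: float = 325.0
    voxel_z_nm: float = 325.0
    n_spheres: int = 8
    sphere_radius_nm: tuple[float, float] = (1300.0, 3250.0)
    n_rods: int = 8
    rod_length_nm: tuple[float, float] = (3250.0, 9750.0)
    rod_radius_nm: tuple[float, float] = (650.0, 1300.0)
    intensity_range: tuple[float, float] = (0.5, 1.0)
    margin_voxels: int = 4
    allow_overlap: bool = False
    seed: int = 0

    @classmethod
    def for_shape(
        cls,
        shape: tuple[int, int, int],
        *,
        voxel_xy_nm: float = 325.0,
        voxel_z_nm: float = 325.0,
        seed: int = 0,
        **overrides,
    ) -> "PhantomSpec":
        """Spec with object sizes scaled proportionally to the grid.

        Object radii and lengths shrink with the smallest grid dimension
        relative to the full-scale 128-plane default, so scaled-down
        benchmark volumes keep the phantom's relative structure.  The
        resulting fine, high-contrast texture is also what makes a good
        modulator for PSF decoupling: its spectrum is broadband, so the
        PSF is constrained at all transferable frequencies.  Radii are
        floored at one lateral voxel so no object vanishes.
        """

        factor = min(min(shape) / 128.0, 1.0)
        rmin = voxel_xy_nm

        def rng_scaled(lo: float, hi: float) -> tuple[float, float]:
            return (max(lo * factor, rmin), max(hi * factor, 2.0 * rmin))

        params = dict(
            shape=tuple(shape),
            voxel_xy_nm=voxel_xy_nm,
            voxel_z_nm=voxel_z_nm,
            sphere_radius_nm=rng_scaled(1300.0, 3250.0),
            rod_length_nm=rng_scaled(3250.0, 9750.0),
            rod_radius_nm=(max(650.0 * factor, rmin / 2), max(1300.0 * factor, rmin)),
            margin_voxels=2 if min(shape) < 64 else 4,
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        if self.n_spheres < 0 or self.n_rods < 0:
            raise ValidationError("object counts must be >= 0")
        if min(self.sphere_radius_nm) <= 0 or min(self.rod_radius_nm) <= 0:
            raise ValidationError("radii must be positive")
        if self.margin_voxels < 0:
            raise ValidationError("margin must be >= 0")
        if not (self.voxel_xy_nm > 0 and self.voxel_z_nm > 0):
            raise ValidationError("voxel sizes must be positive")


@dataclass(frozen=True)
class BeadFieldSpec:
    """Parameters of a sub-diffraction fluorescent bead field."""

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_xy_nm: float = 325.0
    voxel_z_nm: float = 325.0
    bead_diameter_nm: float = 500.0
    n_beads: int = 9
    min_separation_nm: float = 5200.0
    intensity: float = 1.0
    margin_voxels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_diameter_nm <= 0:
            raise ValidationError("bead diameter must be positive")
        if self.min_separation_nm < self.bead_diameter_nm:
            raise ValidationError("separation must be >= bead diameter")
        if self.n_beads < 0:
            raise ValidationError("n_beads must be >= 0")


# ---------------------------------------------------------------------------
# voxel rasterisation helpers (physical nm coordinates, (z, y, x) order)
# ---------------------------------------------------------------------------


def _voxel_scale(spec) -> np.ndarray:
    return np.array([spec.voxel_z_nm, spec.voxel_xy_nm, spec.voxel_xy_nm])


def _sphere_voxels(shape, scale, center_nm, radius_nm):
    """Indices of voxels whose centres fall inside the sphere."""
    lo = np.maximum(np.floor((center_nm - radius_nm) / scale).astype(int), 0)
    hi = np.minimum(np.ceil((center_nm + radius_nm) / scale).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1) * scale
    inside = np.sum((pts - center_nm) ** 2, axis=-1) <= radius_nm**2
    return zz[inside], yy[inside], xx[inside]


def _capsule_voxels(shape, scale, p0_nm, p1_nm, radius_nm):
    """Voxels whose centres lie within ``radius`` of the segment p0-p1."""
    lo_nm = np.minimum(p0_nm, p1_nm) - radius_nm
    hi_nm = np.maximum(p0_nm, p1_nm) + radius_nm
    lo = np.maximum(np.floor(lo_nm / scale).astype(int), 0)
    hi = np.minimum(np.ceil(hi_nm / scale).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return tuple(np.empty(0, dtype=int) for _ in range(3))
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1) * scale
    axis = p1_nm - p0_nm
    seg_len_sq = float(np.dot(axis, axis))
    if seg_len_sq == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(np.tensordot(pts - p0_nm, axis, axes=([-1], [0])) / seg_len_sq, 0, 1)
    nearest = p0_nm + t[..., None] * axis
    inside = np.sum((pts - nearest) ** 2, axis=-1) <= radius_nm**2
    return zz[inside], yy[inside], xx[inside]


def _extent_nm(spec, margin_extra_nm: np.ndarray):
    """Sampling bounds (lo, hi) in nm for object centres given a margin."""
    scale = _voxel_scale(spec)
    size_nm = (np.array(spec.shape) - 1) * scale
    lo = spec.margin_voxels * scale + margin_extra_nm
    hi = size_nm - spec.margin_voxels * scale - margin_extra_nm
    if np.any(lo > hi):
        raise PlacementError("volume too small for requested objects and margin")
    return lo, hi


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> VolumeStack:
    """Render the spheres+rods phantom; deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape, dtype=np.float64)
    scale = _voxel_scale(spec)
    shape = np.array(spec.shape)

    def place(raster):
        """Rejection-sample an object footprint; returns voxel indices."""
        failure = None
        for _ in range(_MAX_TRIES):
            try:
                idx = raster()
            except PlacementError as exc:  # size/orientation infeasible: redraw
                failure = exc
                continue
            if len(idx[0]) == 0:
                continue
            if spec.allow_overlap or not np.any(vol[idx] > 0):
                return idx
        raise PlacementError(
            "could not place object within the margin-shrunk volume"
        ) from failure

    def raster_sphere():
        radius = rng.uniform(*spec.sphere_radius_nm)
        lo, hi = _extent_nm(spec, np.full(3, radius))
        center = rng.uniform(lo, hi)
        return _sphere_voxels(shape, scale, center, radius)

    def raster_rod():
        # orientation first: a rod may fit lying in-plane even when the
        # volume is too thin for it standing upright
        length = rng.uniform(*spec.rod_length_nm)
        radius = rng.uniform(*spec.rod_radius_nm)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        half = direction * (length / 2 - radius)  # caps add the radius
        lo, hi = _extent_nm(spec, np.abs(half) + radius)
        center = rng.uniform(lo, hi)
        return _capsule_voxels(shape, scale, center - half, center + half, radius)

    for _ in range(spec.n_spheres):
        idx = place(raster_sphere)
        vol[idx] = rng.uniform(*spec.intensity_range)

    for _ in range(spec.n_rods):

        idx = place(raster_rod)
        vol[idx] = rng.uniform(*spec.intensity_range)

    return VolumeStack(vol, spec.voxel_xy_nm, spec.voxel_z_nm)


def generate_bead_field(
    spec: BeadFieldSpec,
) -> tuple[VolumeStack, list[tuple[int, int, int]]]:
    """Render a bead field; returns the volume and bead centres (z, y, x voxels).

    Bead centres snap to voxel centres (sub-voxel placement is not
    modelled); the minimum pairwise separation is enforced in nm.
    """

    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape, dtype=np.float64)
    scale = _voxel_scale(spec)
    shape = np.array(spec.shape)
    radius = spec.bead_diameter_nm / 2.0

    centers_nm: list[np.ndarray] = []
    for _ in range(spec.n_beads):
        for _ in range(_MAX_TRIES):
            lo, hi = _extent_nm(spec, np.full(3, radius))
            cand = np.round(rng.uniform(lo, hi) / scale) * scale
            if all(
                np.linalg.norm(cand - c) >= spec.min_separation_nm for c in centers_nm
            ):
                centers_nm.append(cand)
                break
        else:
            raise PlacementError("could not satisfy bead separation constraint")

    centers_vox: list[tuple[int, int, int]] = []
    for center in centers_nm:
        idx = _sphere_voxels(shape, scale, center, radius)
        if len(idx[0]) == 0:  # bead smaller than a voxel: deposit at its voxel
            idx = tuple(np.array([int(round(c / s))]) for c, s in zip(center, scale))
        vol[idx] += spec.intensity
        centers_vox.append(tuple(int(round(c / s)) for c, s in zip(center, scale)))

    return VolumeStack(vol, spec.voxel_xy_nm, spec.voxel_z_nm), centers_vox
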