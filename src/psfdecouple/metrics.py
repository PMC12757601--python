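"""Image-quality metrics: 3D SSIM, NCC, FWHM line profiles, projections."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.ndimage as ndi
from skimage.metrics import structural_similarity

from .errors import ValidationError
from .stacks import VolumeStack

__all__ = ["MetricsReport", "ssim3d", "ncc", "fwhm_line", "project"]


@dataclass
class MetricsReport:
    """Named metric values plus the choices that produced them."""

    values: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {"values": dict(self.values), "provenance": dict(self.provenance)}


def _asarray(x) -> np.ndarray:
    return x.data if isinstance(x, VolumeStack) else np.asarray(x, dtype=np.float64)


def ssim3d(
    a,
    b,
    *,
    data_range: float,
    sigma: float = 1.5,
    slicewise: bool = False,
) -> float:
    """Mean structural similarity between two volumes.

    Uses a Gaussian weighting window (sigma 1.5, 11-voxel support) and the
    standard constants ``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2`` with
    ``L = data_range``.  By default the window is fully 3D; with
    ``slicewise=True`` the SSIM is computed per z-slice in 2D and averaged
    (an alternative convention some tools use).
    """

    a, b = _asarray(a), _asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not data_range > 0:
        raise ValidationError("data_range must be positive")
    kwargs = dict(
        data_range=data_range,
        gaussian_weights=True,
        sigma=sigma,
        use_sample_covariance=False,
    )
    # the Gaussian window spans 11 voxels at sigma 1.5; volumes (or slices)
    # smaller than that fall back to the largest odd window that fits
    min_dim = min(a.shape[1:]) if slicewise else min(a.shape)
    if min_dim < 11:
        win = min_dim if min_dim % 2 == 1 else min_dim - 1
        if win < 3:
            raise ValidationError("volume too small for a windowed SSIM")
        kwargs["win_size"] = win
    if slicewise:
        return float(
            np.mean([structural_similarity(sa, sb, **kwargs) for sa, sb in zip(a, b)])
        )
    return float(structural_similarity(a, b, **kwargs))


def ncc(a, b) -> float:
    """Zero-mean normalised cross-correlation at zero lag, in [-1, 1]."""
    a, b = _asarray(a).ravel(), _asarray(b).ravel()
    if a.shape != b.shape:
        raise ValidationError("shape mismatch")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("NCC undefined for a constant input")
    return float(np.dot(a, b) / (na * nb))


def fwhm_line(
    stack: VolumeStack,
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    *,
    supersample: int = 10,
) -> float:
    """Full width at half maximum along a line profile, in nm.

    ``start`` and ``end`` are (z, y, x) voxel coordinates.  The intensity
    is sampled along the segment by cubic interpolation at ``supersample``
    points per voxel step, peak-normalised, and the width is measured
    between the two half-maximum crossings (linear interpolation between
    samples).  Raises when either crossing is missing (flat or truncated
    profile).
    """

    p0 = np.asarray(start, dtype=np.float64)
    p1 = np.asarray(end, dtype=np.float64)
    for p in (p0, p1):
        if np.any(p < 0) or np.any(p > np.asarray(stack.shape) - 1):
            raise ValidationError("line endpoints must lie inside the volume")
    steps = max(int(np.ceil(np.linalg.norm(p1 - p0))) * supersample, 2)
    t = np.linspace(0.0, 1.0, steps + 1)
    coords = p0[:, None] + (p1 - p0)[:, None] * t[None, :]
    profile = ndi.map_coordinates(stack.data, coords, order=3, mode="nearest")

    peak = profile.max()
    if peak <= 0:
        raise ValidationError("profile has no positive peak")
    profile = profile / peak
    ipk = int(np.argmax(profile))
    half = 0.5

    def crossing(idx_range) -> float:
        prev = None
        for i in idx_range:
            if profile[i] < half:
                j = prev if prev is not None else i
                # linear interpolation between samples i and j
                f_i, f_j = profile[i], profile[j]
                frac = 0.0 if f_j == f_i else (half - f_i) / (f_j - f_i)
                return i + frac * (j - i)
            prev = i
        raise ValidationError("half-maximum crossing not found (truncated profile)")

    left = crossing(range(ipk, -1, -1))
    right = crossing(range(ipk, len(profile)))

    # physical length per unit t, from the anisotropic voxel sizes
    delta_nm = (p1 - p0) * np.array(
        [stack.voxel_z_nm, stack.voxel_xy_nm, stack.voxel_xy_nm]
    )
    length_nm = float(np.linalg.norm(delta_nm))
    return (right - left) / steps * length_nm


def project(stack: VolumeStack, mode: str = "mip", axis: int = 0) -> np.ndarray:
    """2D projection of a stack: maximum intensity or depth of the maximum.

    ``mip`` takes the per-pixel maximum along ``axis``; ``depth_argmax``
    the index of the axial maximum (ties resolve to the smallest index).
    """

    if axis not in (0, 1, 2):
        raise ValidationError("axis must be 0, 1 or 2")
    if mode == "mip":
        return stack.data.max(axis=axis)
    if mode == "depth_argmax":
        return stack.data.argmax(axis=axis)
    raise ValidationError(f"unknown projection mode {mode!r}")
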