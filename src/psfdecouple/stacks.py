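"""In-memory containers for 3D intensity stacks.

Axis convention throughout the package: arrays are indexed ``(z, y, x)``,
0-based, with all physical lengths in nanometres.  The nominal centre voxel
of a stack of shape ``(nz, ny, nx)`` is ``(nz // 2, ny // 2, nx // 2)``
(FFT-centre convention, fixed for even and odd sizes alike).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = ["VolumeStack", "PSFStack", "center_index"]


def center_index(shape: tuple[int, ...]) -> tuple[int, ...]:
    """Nominal centre voxel of a grid: ``floor(n/2)`` per axis."""
    return tuple(int(n) // 2 for n in shape)


@dataclass
class VolumeStack:
    """A 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)``; converted to ``float64``.
    voxel_xy_nm, voxel_z_nm:
        Lateral and axial sampling intervals in nanometres.
    """

    data: np.ndarray
    voxel_xy_nm: float
    voxel_z_nm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValidationError(f"stack must be 3D (z, y, x); got ndim={arr.ndim}")
        if not (self.voxel_xy_nm > 0 and self.voxel_z_nm > 0):
            raise ValidationError("voxel sizes must be positive")
        self.data = arr

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def center(self) -> tuple[int, int, int]:
        return center_index(self.shape)  # type: ignore[return-value]

    def same_grid(self, other: "VolumeStack", *, same_shape: bool = True) -> bool:
        """True when voxel sizes (and optionally shapes) agree."""
        ok = np.isclose(self.voxel_xy_nm, other.voxel_xy_nm) and np.isclose(
            self.voxel_z_nm, other.voxel_z_nm
        )
        if same_shape:
            ok = ok and self.shape == other.shape
        return bool(ok)

    def require_same_grid(self, other: "VolumeStack", *, same_shape: bool = True) -> None:
        if not self.same_grid(other, same_shape=same_shape):
            raise ValidationError(
                f"incompatible grids: {self.shape}@({self.voxel_xy_nm}, "
                f"{self.voxel_z_nm}) nm vs {other.shape}@({other.voxel_xy_nm}, "
                f"{other.voxel_z_nm}) nm"
            )

    def with_data(self, data: np.ndarray) -> "VolumeStack":
        """Copy of this stack carrying new voxel data on the same grid."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class PSFStack(VolumeStack):
    """A point-spread-function stack: non-negative, nominally centred.

    When ``normalized`` is true the voxel sum is 1 (checked to 1e-9
    relative) so that convolution by the PSF conserves total flux.
    """

    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.data < 0):
            raise ValidationError("PSF values must be non-negative")
        if self.normalized:
            total = float(self.data.sum())
            if not np.isclose(total, 1.0, rtol=1e-9, atol=0.0):
                raise ValidationError(f"normalized PSF must sum to 1; got {total!r}")

    @classmethod
    def from_volume(cls, stack: VolumeStack, *, normalize: bool = True) -> "PSFStack":
        data = np.clip(stack.data, 0.0, None)
        if normalize:
            total = data.sum()
            if total <= 0:
                raise ValidationError("cannot normalize an all-zero PSF")
            data = data / total
        return cls(
            data=data,
            voxel_xy_nm=stack.voxel_xy_nm,
            voxel_z_nm=stack.voxel_z_nm,
            normalized=normalize,
        )

    def normalized_copy(self) -> "PSFStack":
        return PSFStack.from_volume(self, normalize=True)
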