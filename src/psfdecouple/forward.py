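"""Image formation: 3D convolution, camera noise, and bead-PSF extraction.

The forward model is ``g = h (x) f`` — a shift-invariant 3D blur — followed
by shot noise and Gaussian read noise.  Convolution is computed by FFT on a
grid padded by half the kernel support; the volume is padded edge-replicate
(a reasonable stand-in for fluorescence continuing past the field of view),
so the result equals exact linear convolution with replicated boundary
values.  A periodic mode (no padding, circular) exists for exact
flux-conservation and adjoint checks.

The kernel's origin is its centre voxel ``floor(n/2)`` per axis, matching
the PSF convention, so a centred delta kernel is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .errors import ExtractionError, ValidationError
from .stacks import PSFStack, VolumeStack, center_index

__all__ = [
    "NoiseSpec",
    "FFTConvolver",
    "convolve3d",
    "simulate_image",
    "extract_bead_psf",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise model: Poisson shot noise plus Gaussian read noise.

    The clean blurred image is scaled so its brightest voxel expects
    ``photon_scale`` photons (an exposure setting: the camera's dynamic
    range is filled regardless of how much the blur dilutes the object),
    Poisson-sampled, then ``Normal(offset, read_sigma)`` counts are added
    and the result is clipped at zero.  With ``normalize_peak=False`` the
    image is instead taken as-is in units of expected photons
    (``counts ~ Poisson(photon_scale * image)``), which keeps the mean
    response exactly linear in the input.
    """

    photon_scale: float = 1000.0
    read_sigma: float = 0.0
    offset: float = 0.0
    seed: int = 0
    normalize_peak: bool = True

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_sigma < 0:
            raise ValidationError("photon_scale and read_sigma must be >= 0")


class FFTConvolver:
    """Same-shape 3D convolution by a fixed kernel, with cached kernel FFTs.

    ``forward(x)`` computes ``x (x) kernel``; ``adjoint(x)`` computes the
    adjoint on the (padded, circular) grid, which equals convolution with
    the kernel reflected through its centre voxel.  Building the object
    once and reusing it amortises the kernel transform across the many
    iterations of a multiplicative deconvolution loop.
    """

    def __init__(
        self,
        kernel: np.ndarray,
        shape: tuple[int, int, int],
        *,
        periodic: bool = False,
        boundary: str = "replicate",
    ) -> None:
        kernel = np.asarray(kernel, dtype=np.float64)
        if kernel.ndim != 3:
            raise ValidationError("kernel must be 3D")
        if any(k > n for k, n in zip(kernel.shape, shape)):
            raise ValidationError(
                f"kernel {kernel.shape} larger than target shape {shape}"
            )
        if boundary not in ("replicate", "zero"):
            raise ValidationError(f"unknown boundary mode {boundary!r}")
        self.shape = tuple(shape)
        self.periodic = periodic
        self.boundary = boundary
        center = center_index(kernel.shape)
        if periodic:
            self.pad = (0, 0, 0)
            work = self.shape
        else:
            self.pad = tuple(k // 2 for k in kernel.shape)
            work = tuple(
                sfft.next_fast_len(n + 2 * p) for n, p in zip(self.shape, self.pad)
            )
        self.work_shape = work
        kbuf = np.zeros(work, dtype=np.float64)
        kbuf[tuple(slice(0, k) for k in kernel.shape)] = kernel
        kbuf = np.roll(kbuf, [-c for c in center], axis=(0, 1, 2))
        self._kfft = sfft.rfftn(kbuf)

    def _embed(self, x: np.ndarray) -> np.ndarray:
        if self.periodic:
            return x
        pad_width = [
            (p, w - n - p) for p, w, n in zip(self.pad, self.work_shape, self.shape)
        ]
        mode = "edge" if self.boundary == "replicate" else "constant"
        return np.pad(x, pad_width, mode=mode)

    def sensitivity(self) -> np.ndarray:
        """Backprojection of a unit image: the EM normaliser.

        Constant (= kernel sum) in the interior; smaller near the
        boundary under zero padding, where part of the kernel support
        falls off-grid.
        """
        return self.adjoint(np.ones(self.shape))

    def _crop(self, x: np.ndarray) -> np.ndarray:
        if self.periodic:
            return x
        sl = tuple(slice(p, p + n) for p, n in zip(self.pad, self.shape))
        return np.ascontiguousarray(x[sl])

    def _apply(self, x: np.ndarray, kfft: np.ndarray) -> np.ndarray:
        if x.shape != self.shape:
            raise ValidationError(f"expected shape {self.shape}, got {x.shape}")
        buf = sfft.rfftn(self._embed(np.asarray(x, dtype=np.float64)))
        buf *= kfft
        return self._crop(sfft.irfftn(buf, s=self.work_shape))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self._apply(x, self._kfft)

    def adjoint(self, x: np.ndarray) -> np.ndarray:
        return self._apply(x, np.conj(self._kfft))


def _clamp_nonneg(out: np.ndarray, *inputs: np.ndarray) -> np.ndarray:
    """Clip tiny negative FFT residue when all inputs are non-negative."""
    if all(np.all(arr >= 0) for arr in inputs):
        floor = -1e-9 * max(float(out.max(initial=0.0)), 1.0)
        if float(out.min(initial=0.0)) < floor:
            raise ValidationError("convolution produced significantly negative values")
        np.clip(out, 0.0, None, out=out)
    return out


def convolve3d(
    f: VolumeStack, h: PSFStack | VolumeStack, *, periodic: bool = False
) -> VolumeStack:
    """Blur ``f`` by the kernel ``h`` (same-shape output).

    ``h`` may be smaller than ``f``; its centre voxel is the kernel origin.
    Voxel sizes of the two stacks must agree.
    """

    f.require_same_grid(h, same_shape=False)
    conv = FFTConvolver(h.data, f.shape, periodic=periodic)
    out = conv.forward(f.data)
    _clamp_nonneg(out, f.data, h.data)
    return f.with_data(out)


def simulate_image(
    f: VolumeStack,
    h: PSFStack,
    noise: NoiseSpec | None = None,
    *,
    peak_reference: float | None = None,
) -> VolumeStack:
    """Simulate a camera acquisition of object ``f`` through PSF ``h``.

    With ``noise=None`` the clean blurred volume is returned (the infinite
    photon-budget limit).  Otherwise Poisson/Gaussian noise is applied,
    deterministically per ``noise.seed``; the output is in camera counts.

    ``peak_reference`` pins the exposure to an external intensity: that
    intensity (instead of this image's own peak) maps to ``photon_scale``
    expected photons.  Passing the peak of a *reference* acquisition
    simulates imaging two samples of very different brightness — e.g.
    sub-diffraction beads versus an extended sample — under the same
    illumination and exposure, which is what a matched photon budget
    means physically.
    """

    blurred = convolve3d(f, h)
    if noise is None:
        return blurred
    rng = np.random.default_rng(noise.seed)
    clean = np.clip(blurred.data, 0, None)
    if peak_reference is not None:
        if not peak_reference > 0:
            raise ValidationError("peak_reference must be positive")
        clean = clean / peak_reference
    elif noise.normalize_peak and clean.max() > 0:
        clean = clean / clean.max()
    counts = rng.poisson(noise.photon_scale * clean).astype(np.float64)
    counts += rng.normal(noise.offset, noise.read_sigma, size=counts.shape)
    return blurred.with_data(np.clip(counts, 0.0, None))


def _border_shell(window: np.ndarray) -> np.ndarray:
    """Values on the outermost 1-voxel shell of a 3D window."""
    mask = np.zeros(window.shape, dtype=bool)
    mask[[0, -1], :, :] = True
    mask[:, [0, -1], :] = True
    mask[:, :, [0, -1]] = True
    return window[mask]


def extract_bead_psf(
    image: VolumeStack,
    centers: list[tuple[int, int, int]],
    window: int | tuple[int, int, int],
) -> PSFStack:
    """Emulate direct PSF measurement from a bead-field acquisition.

    For every bead centre whose window fits inside the volume, a window of
    the given voxel size is cropped, a background estimate (median of the
    window's outermost shell) is subtracted, negatives are clamped, and the
    windows are averaged and normalised to unit sum.  Beads too close to
    the boundary are dropped; if none remain an :class:`ExtractionError`
    is raised.
    """

    if len(centers) == 0:
        raise ExtractionError("no bead centres supplied")
    if isinstance(window, int):
        window = (window, window, window)
    if any(w < 3 or w % 2 == 0 for w in window):
        raise ValidationError("window sizes must be odd and >= 3")
    half = tuple(w // 2 for w in window)

    accum = np.zeros(window, dtype=np.float64)
    retained = 0
    for center in centers:
        lo = [c - hw for c, hw in zip(center, half)]
        hi = [c + hw + 1 for c, hw in zip(center, half)]
        if any(l < 0 for l in lo) or any(h > n for h, n in zip(hi, image.shape)):
            continue
        crop = image.data[tuple(slice(l, h) for l, h in zip(lo, hi))]
        background = float(np.median(_border_shell(crop)))
        accum += np.clip(crop - background, 0.0, None)
        retained += 1
    if retained == 0:
        raise ExtractionError("no bead window fits inside the volume")

    return PSFStack.from_volume(
        VolumeStack(accum / retained, image.voxel_xy_nm, image.voxel_z_nm),
        normalize=True,
    )
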