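"""Richardson-Lucy deconvolution and the alternating blind baseline.

The multiplicative update

``f_{k+1} = { [ g / (h (x) f_k) ] (x) B(h) } . f_k``

is the expectation-maximisation step for a Poisson imaging model; ``B(.)``
is the backprojection operator — convolution with the kernel reflected
through its centre voxel, i.e. the adjoint of the blur.  The same update
with the roles of PSF and object swapped drives both the blind baseline
here and the sample-prior PSF estimation in :mod:`psfdecouple.decouple`.

Bare ratios are stabilised by flooring the denominator at
``epsilon * max(g)``; with non-negative inputs the iteration then preserves
non-negativity exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .forward import FFTConvolver
from .stacks import PSFStack, VolumeStack, center_index

__all__ = [
    "RLConfig",
    "BlindConfig",
    "backproject",
    "rl_deconvolve",
    "blind_deconvolve",
    "poisson_fidelity",
    "gaussian_kernel",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RLConfig:
    """Settings for the Richardson-Lucy loop.

    ``init_mode`` chooses the starting estimate: ``observed`` (f_0 = g,
    standard practice) or ``flat`` (constant volume of matching flux).
    """

    iterations: int = 50
    epsilon: float = 1e-12
    init_mode: str = "observed"
    clamp_nonnegative: bool = True
    periodic: bool = False
    track_fidelity: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not self.epsilon > 0:
            raise ValidationError("epsilon must be > 0")
        if self.init_mode not in ("observed", "flat"):
            raise ValidationError(f"unknown init_mode {self.init_mode!r}")


@dataclass(frozen=True)
class BlindConfig:
    """Settings for alternating blind deconvolution (bPSF baseline)."""

    outer: int = 20
    inner_f: int = 5
    inner_h: int = 5
    epsilon: float = 1e-12
    h_shape: tuple[int, int, int] | None = None
    h_sigma_voxels: float = 3.0  # width of the Gaussian PSF initialiser
    divergence_patience: int = 5

    def __post_init__(self) -> None:
        if min(self.outer, self.inner_f, self.inner_h) < 1:
            raise ValidationError("iteration counts must be >= 1")


def backproject(h: PSFStack | VolumeStack | np.ndarray):
    """Reflect a kernel through its centre voxel along all three axes.

    This is the adjoint kernel of convolution by ``h`` under the
    centre-voxel-origin convention: index ``i`` maps to ``(2c - i) mod n``
    with ``c = n // 2``, which reduces to a plain flip on odd-sized axes
    and a flip followed by a one-voxel roll on even-sized ones.
    """

    arr = h.data if isinstance(h, VolumeStack) else np.asarray(h)
    out = arr[::-1, ::-1, ::-1]
    even_axes = [ax for ax, n in enumerate(arr.shape) if n % 2 == 0]
    if even_axes:
        out = np.roll(out, shift=[1] * len(even_axes), axis=even_axes)
    out = np.ascontiguousarray(out)
    if isinstance(h, VolumeStack):
        return h.with_data(out)
    return out


def poisson_fidelity(g: np.ndarray, est: np.ndarray) -> float:
    """Generalised KL divergence of the data from the model prediction.

    ``D(g || est) = sum g log(g/est) - g + est`` with the usual
    ``0 log 0 = 0`` convention; non-increasing over RL iterations on
    noise-free data.
    """

    est = np.clip(est, 1e-300, None)
    pos = g > 0
    term = np.zeros_like(est)
    term[pos] = g[pos] * np.log(g[pos] / est[pos])
    return float(np.sum(term - g + est))


def _rl_loop(
    g: np.ndarray,
    conv: FFTConvolver,
    x0: np.ndarray,
    iterations: int,
    eps_abs: float,
    clamp: bool,
    fidelity: list[float] | None,
) -> np.ndarray:
    """Core multiplicative loop shared by RL, blind and PSF decoupling."""
    x = np.asarray(x0, dtype=np.float64).copy()
    for _ in range(iterations):
        est = conv.forward(x)
        ratio = g / np.maximum(est, eps_abs)
        x *= conv.adjoint(ratio)
        if clamp:
            np.clip(x, 0.0, None, out=x)
        if fidelity is not None:
            fidelity.append(poisson_fidelity(g, est))
    return x


def rl_deconvolve(
    g: VolumeStack,
    h: PSFStack,
    cfg: RLConfig | None = None,
) -> VolumeStack:
    """Deconvolve ``g`` by the known PSF ``h`` (Richardson-Lucy).

    Returns the deblurred volume; per-iteration Poisson fidelities are
    attached as ``result.fidelity`` when ``cfg.track_fidelity`` is set.
    """

    cfg = cfg or RLConfig()
    g.require_same_grid(h, same_shape=False)
    if not np.all(np.isfinite(g.data)) or not np.all(np.isfinite(h.data)):
        raise ValidationError("inputs must be finite")
    conv = FFTConvolver(h.data, g.shape, periodic=cfg.periodic)
    if cfg.init_mode == "observed":
        f0 = g.data
    else:
        f0 = np.full(g.shape, float(g.data.mean()))
    eps_abs = cfg.epsilon * float(g.data.max(initial=0.0))
    fidelity: list[float] | None = [] if cfg.track_fidelity else None
    f = _rl_loop(
        g.data, conv, f0, cfg.iterations, eps_abs, cfg.clamp_nonnegative, fidelity
    )
    result = g.with_data(f)
    if fidelity is not None:
        result.fidelity = fidelity  # type: ignore[attr-defined]
        log.info(
            "RL finished: %d iterations, final fidelity %.6g",
            cfg.iterations,
            fidelity[-1],
        )
    else:
        log.info("RL finished: %d iterations", cfg.iterations)
    return result


def gaussian_kernel(
    shape: tuple[int, int, int],
    sigma_voxels: float,
    voxel_xy_nm: float,
    voxel_z_nm: float,
) -> PSFStack:
    """Unit-sum isotropic (in voxels) Gaussian kernel, centred."""
    grids = [np.arange(n) - n // 2 for n in shape]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    data = np.exp(-(zz**2 + yy**2 + xx**2) / (2.0 * sigma_voxels**2))
    stack = VolumeStack(data, voxel_xy_nm, voxel_z_nm)
    return PSFStack.from_volume(stack, normalize=True)


def _crop_center(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    sl = tuple(
        slice(n // 2 - k // 2, n // 2 - k // 2 + k) for n, k in zip(arr.shape, shape)
    )
    return np.ascontiguousarray(arr[sl])


def _embed_center(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float64)
    sl = tuple(
        slice(n // 2 - k // 2, n // 2 - k // 2 + k) for n, k in zip(shape, arr.shape)
    )
    out[sl] = arr
    return out


def blind_deconvolve(
    g: VolumeStack,
    cfg: BlindConfig | None = None,
    h_init: PSFStack | None = None,
    f_init: VolumeStack | None = None,
) -> tuple[VolumeStack, PSFStack]:
    """Alternating blind deconvolution: jointly estimate object and PSF.

    Outer cycles alternate ``inner_f`` RL updates of the object (PSF held
    fixed) with ``inner_h`` multiplicative updates of the PSF (object held
    fixed, same update form as sample-prior PSF estimation), renormalising
    the PSF to unit sum after every cycle.  Without any prior on the PSF
    the problem is highly ill-posed — this is the bPSF baseline the
    sample-prior method is compared against, not a recommended tool.

    If the Poisson fidelity increases for ``divergence_patience``
    consecutive outer cycles a warning is emitted and iteration stops.
    """

    cfg = cfg or BlindConfig()
    h_shape = cfg.h_shape or g.shape
    if h_init is None:
        h_init = gaussian_kernel(h_shape, cfg.h_sigma_voxels, g.voxel_xy_nm, g.voxel_z_nm)
    h = h_init.data.copy()
    h_shape = h.shape
    f = (f_init.data if f_init is not None else g.data).copy()
    eps_abs = cfg.epsilon * float(g.data.max(initial=0.0))

    conv_f = FFTConvolver(f, g.shape)  # kernel = current object estimate
    last_fid = np.inf
    rising = 0
    for cycle in range(cfg.outer):
        # --- object step: RL with h fixed
        conv_h = FFTConvolver(h, g.shape)
        f = _rl_loop(g.data, conv_h, f, cfg.inner_f, eps_abs, True, None)
        # --- PSF step: multiplicative update with f fixed as the kernel
        # (zero boundary + sensitivity: the PSF does not extend off-grid)
        conv_f = FFTConvolver(f, g.shape, boundary="zero")
        sens = np.maximum(conv_f.sensitivity(), 1e-12 * float(f.sum() + 1e-300))
        h_full = _embed_center(h, g.shape)
        for _ in range(cfg.inner_h):
            est = conv_f.forward(h_full)
            ratio = g.data / np.maximum(est, eps_abs)
            h_full *= conv_f.adjoint(ratio) / sens
            np.clip(h_full, 0.0, None, out=h_full)
            h_full = _embed_center(_crop_center(h_full, h_shape), g.shape)
            total = h_full.sum()
            if total > 0:
                h_full /= total
        h = _crop_center(h_full, h_shape)

        fid = poisson_fidelity(g.data, conv_f.forward(_embed_center(h, g.shape)))
        rising = rising + 1 if fid > last_fid else 0
        last_fid = fid
        if rising >= cfg.divergence_patience:
            warnings.warn(
                f"blind deconvolution diverging; stopped after {cycle + 1} cycles",
                RuntimeWarning,
                stacklevel=2,
            )
            break

    total = h.sum()
    if total <= 0:
        raise ValidationError("blind deconvolution collapsed to an empty PSF")
    h_stack = PSFStack(h / total, g.voxel_xy_nm, g.voxel_z_nm, normalized=True)
    return g.with_data(f), h_stack
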