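# psfdecouple

Sample-prior point-spread-function (PSF) decoupling for computational
fluorescence microscopy, with the full simulation stack needed to study it:
pupil-plane optics, synthetic phantoms, a camera forward model,
Richardson–Lucy deconvolution, a blind-deconvolution baseline, and 3D
image-quality metrics.

## The problem

Wide-field fluorescence microscopes that add active optical modulation —
annular aperture masks for extended depth of field, amplitude gating of the
pupil, deliberate phase modulation — gain imaging capabilities but lose the
one thing deconvolution depends on: an accurate system PSF. Theoretical
models rarely match a modulated system, and measuring the PSF directly with
sub-diffraction beads fails at depth because the bead signal is tiny
(low SNR). Blind deconvolution, which estimates PSF and object jointly, is
badly ill-posed.

## The method

Image formation is the shift-invariant blur `g = h ⊗ f`. The idea is to use
an ordinary, structured fluorescent sample as a *modulator* and image it
twice:

1. **Wide-field shot** `g_wf` through the unmodulated system, whose
   theoretical PSF `h_theo` is reliable. Richardson–Lucy deconvolution
   yields the *sample prior*:

   `f_{k+1} = { [ g_wf / (h_theo ⊗ f_k) ] ⊗ B(h_theo) } · f_k  →  f*_wf`

2. **Modulated shot** `g_mod` of the *same* sample through the system whose
   PSF is wanted. Holding `f*_wf` fixed, the same multiplicative update —
   with the roles of object and kernel swapped — recovers the
   *computational PSF* (cPSF):

   `h_{k+1} = { [ g_mod / (h_k ⊗ f*_wf) ] ⊗ B(f*_wf) } · h_k  →  h*_comp`

`B(·)` is backprojection (convolution with the spatially reflected kernel —
the adjoint of the blur). Because one factor of the bilinear model is
pinned by the prior, PSF estimation becomes a well-posed Poisson inverse
problem; the cPSF then drives ordinary PSF-known deconvolution of any other
stack acquired on the modulated system.

## Worked example

```python
import numpy as np
from psfdecouple import (
    ApertureModulation, DecoupleConfig, NoiseSpec, OpticalConfig,
    PhantomSpec, generate_phantom, make_pupil, ncc, psf_from_pupil,
    run_decouple_pipeline, simulate_image,
)

optics = OpticalConfig(na=0.75, wavelength_nm=570, voxel_xy_nm=325,
                       voxel_z_nm=325, nx=64, ny=64, nz=32)
h_wf = psf_from_pupil(make_pupil(optics))                 # open pupil
h_true = psf_from_pupil(make_pupil(                        # annular mask
    optics, ApertureModulation("annular", obstruction_ratio=0.8)))

modulator = generate_phantom(PhantomSpec.for_shape((32, 64, 64), seed=3))
g_wf = simulate_image(modulator, h_wf, NoiseSpec(1000, 2.0, 0.0, seed=11))
g_mod = simulate_image(modulator, h_true, NoiseSpec(1000, 2.0, 0.0, seed=12))

result = run_decouple_pipeline(g_wf, h_wf, g_mod, DecoupleConfig())
print(f"NCC(cPSF, true PSF) = {ncc(result.cpsf.data, h_true.data):.4f}")
print(f"residual NCC        = {result.residual_ncc:.4f}")
```

Output:

```
NCC(cPSF, true PSF) = 0.9751
residual NCC        = 0.9923
```

The first number says the decoupled PSF matches the true annular-aperture
PSF to NCC 0.97 from two noisy simulated acquisitions (about 1000 photons
at the brightest voxel); the second says the factorisation
`cPSF ⊗ prior` explains 99% of the modulated signal's variance.

A command-line interface mirrors the library
(`psfdecouple psf | phantom | simulate | deconvolve | blind | decouple |
evaluate | bench-fig2`); every command writes a JSON run manifest with
config, seeds and file digests next to its outputs.

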