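# Methods

## Optical model

The microscope is modelled by a scalar complex pupil sampled on the image's
transverse spatial-frequency grid. The aperture indicator (clear disc,
annulus with inner/outer diameter ratio *ε*, or a 4×4-gated disc emulating
random amplitude modulation) sets the pupil amplitude; phase aberrations
are expressed on the Noll-indexed, RMS-normalised Zernike basis, so a term
with coefficient *c* contributes *c* radians RMS over the pupil disc. The
3D intensity PSF follows by angular-spectrum propagation: plane *z* is
`|F⁻¹[ P(k) · exp(i·2π·z·k_z) ]|²` with
`k_z = sqrt((n/λ)² − k_x² − k_y²)` on the pupil support. The model is
scalar and aplanatic: no vectorial (Richards–Wolf) high-NA correction and
no index-mismatch (Gibson–Lanni) depth dependence. That is adequate for the
NA 0.75 air objective regime this package simulates; at NA ≳ 1 the scalar
approximation underestimates the axial extent and polarisation effects.

Conventions, fixed throughout: arrays are `(z, y, x)`, 0-based; the
nominal centre voxel of any stack or kernel is `floor(n/2)` per axis
(FFT-centre convention, for even and odd sizes alike); all physical
lengths are nanometres; PSFs are normalised to unit sum over the finite
stack, so convolution conserves flux.

A note on the annular aperture: its defocused PSF keeps a Bessel-like
on-axis core over a surprisingly long range — that *is* the
depth-of-field extension — so the familiar "hollow cone" picture is
energetic, not peak-wise. Only past roughly ten voxels of defocus (at
325 nm sampling, NA 0.75, ε = 0.8) does the off-axis ring dominate; the
tests assert ring-ness there, by energy fraction and by the off-axis peak
of the azimuthally averaged profile.

## Forward model

Image formation is `g = h ⊗ f` computed by FFT on a grid padded by half
the kernel support. The *object* is padded edge-replicate (fluorescence
does not stop at the field of view), which makes constants exact
eigenfunctions of the blur — a property the Richardson–Lucy flux balance
relies on. A periodic mode exists for exact conservation and adjoint
checks. The kernel origin is its centre voxel, so a centred delta is the
identity.

Camera noise is Poisson shot noise plus Gaussian read noise:
`counts = clip(Poisson(s·g) + N(offset, σ_read), 0)`. The gain `s` is an
exposure setting: by default it maps the brightest voxel of the clean
image to `photon_scale` expected photons, the way a camera's dynamic range
is actually filled. For experiments that compare samples of different
intrinsic brightness under one illumination — the bead field versus the
extended phantom — `simulate_image(..., peak_reference=...)` pins the gain
to a reference acquisition instead; the bead field then lands several
times dimmer, which is precisely the physical handicap of direct bead
measurement. An unnormalised mode (`normalize_peak=False`) keeps
`E[counts] = photon_scale·g + offset` exactly linear for statistical
checks.

## Deconvolution and PSF estimation

Richardson–Lucy is the multiplicative EM update for the Poisson model,

    f_{k+1} = { [ g / (h ⊗ f_k) ] ⊗ B(h) } · f_k ,

with the denominator floored at `ε·max(g)` (ε = 1e-12) and `f_0 = g`.
Backprojection `B(·)` reflects a kernel through its centre voxel — a plain
flip on odd axes, flip plus one-voxel roll on even ones — and equals the
adjoint of the circular blur. No regularisation is applied; iteration
count is the only stopping control (default 50 for wide-field priors).

PSF estimation from a fixed sample prior swaps the roles of object and
kernel. One refinement matters here: the PSF estimate, unlike the object,
has no existence outside the reconstructed grid, so its forward blur uses
**zero** boundary padding, and the multiplicative update is normalised by
the EM *sensitivity image* (the backprojection of ones) rather than the
constant `sum(f_prior)`. In the interior the two coincide exactly (after
the per-iteration unit-sum renormalisation); near the stack boundary the
sensitivity correction is what makes the true PSF an exact fixed point of
the iteration and measurably improves recovery (noise-free NCC 0.998
versus 0.975 at 200 iterations on the annular benchmark). Constraints per
iteration: non-negativity clamp, unit-sum renormalisation (fixes the scale
ambiguity of the bilinear model; on by default), optional centred support
box, optional final centroid recentering (off by default — a genuinely
off-centre system response is information, and the factorisation carries a
joint shift ambiguity between prior and PSF that tests document as shift
covariance).

The blind baseline alternates short inner runs of the object update (PSF
fixed) and the PSF update (object fixed), renormalising the PSF each
cycle, from a wide Gaussian initialisation. It exists as the comparison
point the sample-prior method is measured against; it inherits all the
ill-posedness the prior removes. A divergence guard (Poisson fidelity
rising for five consecutive cycles) stops it with a warning.

## Synthetic data

The modulator phantom is a sparse field of solid spheres and
capsule-shaped rods (uniform random positions, orientations and
intensities in [0.5, 1.0], margin-confined, overlap rejected with bounded
retries). Full-scale defaults follow the simulation conditions the package
targets: a 256×256×128 grid at 325 nm isotropic sampling, 8 spheres of
4–10 voxel radius and 8 rods. `PhantomSpec.for_shape` scales object sizes
proportionally to the grid for desk-scale runs. The fine, high-contrast
texture of the scaled phantom is deliberate: a modulator constrains the
PSF only at frequencies its own spectrum covers, and small broadband
objects make the stage-2 iteration converge in a few hundred iterations
where large smooth objects (spectrum concentrated at low frequencies)
need thousands. Rasterisation is by voxel-centre inclusion — object counts
and volumes are exact, at the cost of aliased edges; no partial-volume
antialiasing.

The bead field renders 500 nm spheres (at 325 nm sampling, a single-voxel
footprint) on a minimum-separation grid, returning ground-truth centres.
Bead centres snap to voxel centres; sub-voxel localisation is not
modelled, which flatters the emulated bead measurement slightly relative
to real bead data.

What the generators do *not* emulate: tissue texture and scattering,
refractive-index heterogeneity, spatially varying blur, photobleaching,
camera fixed-pattern noise. Passing tests therefore demonstrate the
algorithmic mechanism — prior-anchored PSF recovery beating direct
measurement and blind estimation under shot noise — not performance on
real tissue.

## Metrics

3D SSIM uses a Gaussian window (σ = 1.5, 11³ support) with the standard
constants `C1 = (0.01·L)²`, `C2 = (0.03·L)²`; volumes are min–max
normalised to [0, 1] before comparison (data range 1), recorded in the
report provenance. A slice-wise 2D-averaged variant is available behind a
flag since published SSIM values do not always state which convention was
used. NCC is zero-mean normalised cross-correlation at zero lag. FWHM is
measured on cubic-interpolated line profiles with linear interpolation
between the half-maximum crossings, converted to nm through the
(anisotropic) voxel sizes.

## Study conditions and problem sizes

The shipped studies run at desk scale on one CPU core: PSF recovery on
64×64×32 (annular ε = 0.8, noise-free plus a 3-seed noisy pipeline at
~1000 photons peak), the bead-versus-cPSF comparison at 100 photons peak
over 5 seeds with a (15, 17, 17) scoring window, and the
modulation/demodulation benchmark with a 128×128×64 test volume, a
64×64×32 modulator, and PSFs cropped to 31³ kernels for the final
deconvolutions. The full-scale 256×256×128 protocol is the same code path
(`BenchConfig()` defaults); `bench-fig2 --ground-truth` accepts an
external volume such as the DeconvolutionLab2 sample for benchmarking
against published reconstruction scores.

## Known limitations

- Shift-invariant blur only; no spatially varying PSF.
- The two acquisitions of the modulator are assumed co-registered; no
  registration step is provided.
- The sample prior is the plain wide-field deconvolution; no prior
  modification/refinement step is implemented.
- Blind baseline is the textbook alternating scheme, not a tuned
  commercial semi-blind implementation.
- Scalar optics (see above); emission-side PSF only.
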