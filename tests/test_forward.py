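"""Forward imaging model: convolution, noise, bead-PSF extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psfdecouple import (
    BeadFieldSpec,
    ExtractionError,
    NoiseSpec,
    PSFStack,
    ValidationError,
    VolumeStack,
    convolve3d,
    extract_bead_psf,
    generate_bead_field,
    ncc,
    simulate_image,
)
from psfdecouple.bench import crop_psf


def vol(data, vx=325.0, vz=325.0):
    return VolumeStack(np.asarray(data, dtype=float), vx, vz)


def brute_force_convolve(f, h):
    """O(N*K) spatial-domain linear convolution with edge-replicate padding."""
    pads = [k // 2 for k in h.shape]
    fp = np.pad(f, [(p, p) for p in pads], mode="edge")
    out = np.zeros_like(f)
    centers = [k // 2 for k in h.shape]
    for jz in range(h.shape[0]):
        for jy in range(h.shape[1]):
            for jx in range(h.shape[2]):
                oz = pads[0] + centers[0] - jz
                oy = pads[1] + centers[1] - jy
                ox = pads[2] + centers[2] - jx
                out += h[jz, jy, jx] * fp[
                    oz : oz + f.shape[0], oy : oy + f.shape[1], ox : ox + f.shape[2]
                ]
    return out


class TestConvolve3d:
    def test_centered_delta_is_identity(self, rng):
        f = vol(rng.random((8, 9, 10)))
        delta = np.zeros((5, 5, 5))
        delta[2, 2, 2] = 1.0
        out = convolve3d(f, vol(delta))
        assert np.allclose(out.data, f.data, rtol=1e-9)

    def test_even_sized_delta_kernel_is_identity(self, rng):
        # centre-voxel convention must hold on even axes too
        f = vol(rng.random((8, 8, 8)))
        delta = np.zeros((4, 6, 6))
        delta[2, 3, 3] = 1.0
        assert np.allclose(convolve3d(f, vol(delta)).data, f.data, rtol=1e-9)

    def test_flux_conservation_periodic(self, rng):
        f = vol(rng.random((6, 8, 8)))
        h = vol(rng.random((3, 3, 3)))
        out = convolve3d(f, h, periodic=True)
        assert out.data.sum() == pytest.approx(f.data.sum() * h.data.sum(), rel=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        f = rng.random((5, 7, 7))
        h = rng.random((3, 3, 3))
        out = convolve3d(vol(f), vol(h))
        assert np.abs(out.data - brute_force_convolve(f, h)).max() < 1e-10

    def test_voxel_size_mismatch_rejected(self, rng):
        f = vol(rng.random((4, 4, 4)), vx=325.0)
        h = vol(rng.random((3, 3, 3)), vx=100.0)
        with pytest.raises(ValidationError):
            convolve3d(f, h)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        a=st.floats(0.1, 5.0),
        b=st.floats(0.1, 5.0),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        f1, f2 = r.random((4, 6, 6)), r.random((4, 6, 6))
        h = vol(r.random((3, 3, 3)))
        lhs = convolve3d(vol(a * f1 + b * f2), h).data
        rhs = a * convolve3d(vol(f1), h).data + b * convolve3d(vol(f2), h).data
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


class TestSimulateImage:
    def test_no_noise_returns_clean_convolution(self, rng):
        f = vol(rng.random((6, 8, 8)))
        h = PSFStack.from_volume(vol(rng.random((3, 3, 3))))
        assert np.array_equal(simulate_image(f, h, None).data,
                              convolve3d(f, h).data)

    def test_same_seed_identical_output(self, rng):
        f = vol(rng.random((6, 8, 8)))
        h = PSFStack.from_volume(vol(rng.random((3, 3, 3))))
        a = simulate_image(f, h, NoiseSpec(500, 2.0, 10.0, seed=3))
        b = simulate_image(f, h, NoiseSpec(500, 2.0, 10.0, seed=3))
        assert np.array_equal(a.data, b.data)

    def test_monte_carlo_mean_matches_model(self, rng):
        # unnormalised mode: E[counts] = photon_scale * (h (x) f) + offset
        f = vol(rng.random((4, 6, 6)) + 0.5)
        h = PSFStack.from_volume(vol(rng.random((3, 3, 3))))
        clean = convolve3d(f, h).data
        ps, offset = 200.0, 50.0
        voxel = (2, 3, 3)
        reps = np.array([
            simulate_image(
                f, h, NoiseSpec(ps, 1.0, offset, seed=k, normalize_peak=False)
            ).data[voxel]
            for k in range(200)
        ])
        expected = ps * clean[voxel] + offset
        sem = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - expected) < 3 * sem + 1e-9


class TestExtractBeadPSF:
    def test_noise_free_beads_recover_true_psf(self, h_annular):
        window = (15, 17, 17)
        beads, centers = generate_bead_field(BeadFieldSpec(shape=(32, 64, 64), seed=7))
        image = simulate_image(beads, h_annular, None)
        est = extract_bead_psf(image, centers, window)
        assert ncc(est.data, crop_psf(h_annular, window).data) >= 0.99

    def test_empty_center_list_raises(self, rng):
        with pytest.raises(ExtractionError):
            extract_bead_psf(vol(rng.random((8, 8, 8))), [], 3)

    def test_all_boundary_beads_raises(self, rng):
        with pytest.raises(ExtractionError):
            extract_bead_psf(vol(rng.random((8, 8, 8))), [(0, 0, 0)], 7)

    def test_recovery_degrades_as_photons_decrease(self, h_annular):
        # the qualitative low-SNR failure mode of direct bead measurement
        window = (15, 17, 17)
        truth = crop_psf(h_annular, window).data
        medians = []
        for ps in (2000.0, 100.0, 20.0):
            scores = []
            for seed in range(5):
                beads, centers = generate_bead_field(
                    BeadFieldSpec(shape=(32, 64, 64), seed=seed)
                )
                image = simulate_image(beads, h_annular, NoiseSpec(ps, 2.0, 0.0, seed))
                scores.append(ncc(extract_bead_psf(image, centers, window).data, truth))
            medians.append(np.median(scores))
        assert medians[0] >= medians[1] >= medians[2]

    def test_background_variance_scales_inversely_with_bead_count(self):
        # averaging n independent bead windows shrinks background noise ~1/n;
        # a compact Gaussian system PSF keeps the window shell signal-free
        # so the shell variance is pure noise
        from psfdecouple import gaussian_kernel

        h = gaussian_kernel((7, 7, 7), 1.0, 325.0, 325.0)
        variances = []
        counts = (1, 4, 16)
        for n in counts:
            per_seed = []
            for seed in range(3):
                beads, centers = generate_bead_field(
                    BeadFieldSpec(shape=(32, 64, 64), n_beads=n,
                                  min_separation_nm=4200.0, seed=seed)
                )
                image = simulate_image(
                    beads, h, NoiseSpec(50.0, 2.0, 0.0, seed + 10)
                )
                est = extract_bead_psf(image, centers, (9, 9, 9))
                shell = np.concatenate([
                    est.data[0].ravel(), est.data[-1].ravel(),
                    est.data[:, 0].ravel(), est.data[:, -1].ravel(),
                    est.data[:, :, 0].ravel(), est.data[:, :, -1].ravel(),
                ])
                per_seed.append(shell.var())
            variances.append(np.mean(per_seed))
        slope = np.polyfit(np.log(counts), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)
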