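"""Pupil construction, Zernike phase, and scalar PSF propagation."""

import numpy as np
import pytest
from scipy.special import j0

from psfdecouple import (
    AberrationSpec,
    ApertureModulation,
    EmptyApertureError,
    OpticalConfig,
    ValidationError,
    fwhm_line,
    make_pupil,
    noll_to_nm,
    psf_from_pupil,
    zernike_phase,
)


def small_config(**kw):
    base = dict(na=0.75, wavelength_nm=570.0, voxel_xy_nm=325.0, voxel_z_nm=325.0,
                nx=64, ny=64, nz=32)
    base.update(kw)
    return OpticalConfig(**base)


class TestOpticalConfig:
    def test_na_must_not_exceed_medium_index(self):
        with pytest.raises(ValidationError):
            small_config(na=1.2, refractive_index=1.0)

    def test_undersampling_warns_but_does_not_error(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            OpticalConfig(na=0.75, wavelength_nm=570.0, voxel_xy_nm=325.0,
                          voxel_z_nm=325.0, nx=8, ny=8, nz=4)

    def test_nyquist_sampling_does_not_warn(self, recwarn):
        small_config(voxel_xy_nm=150.0)
        assert not any("Nyquist" in str(w.message) for w in recwarn.list)


class TestMakePupil:
    def test_open_mode_equals_disc_indicator(self):
        cfg = small_config()
        pupil = make_pupil(cfg)
        ky, kx = cfg.frequency_grid()
        disc = np.hypot(ky, kx) <= cfg.cutoff
        assert np.array_equal(pupil.support, disc)
        assert np.all(pupil.field[~disc] == 0)

    def test_annular_open_area_fraction_matches_analytic(self):
        # open area of an annulus with obstruction e is (1 - e^2) of the disc
        cfg = small_config(nx=256, ny=256, nz=2)
        full = make_pupil(cfg).support.sum()
        ann = make_pupil(
            cfg, ApertureModulation("annular", obstruction_ratio=0.8)
        ).support.sum()
        assert ann / full == pytest.approx(1 - 0.8**2, abs=0.02)

    def test_grid_all_cells_open_equals_open_pupil(self):
        cfg = small_config()
        mod = ApertureModulation("grid", grid_mask=np.ones((4, 4), dtype=bool))
        assert np.array_equal(make_pupil(cfg, mod).field, make_pupil(cfg).field)

    def test_all_gated_mask_raises_empty_aperture(self):
        with pytest.raises(EmptyApertureError):
            ApertureModulation("grid", grid_mask=np.zeros((4, 4), dtype=bool))

    def test_obstruction_ratio_one_rejected(self):
        with pytest.raises(ValidationError):
            ApertureModulation("annular", obstruction_ratio=1.0)

    def test_grid_seed_is_deterministic(self):
        cfg = small_config()
        mod = ApertureModulation("grid", grid_seed=7)
        a = make_pupil(cfg, mod)
        b = make_pupil(cfg, ApertureModulation("grid", grid_seed=7))
        assert np.array_equal(a.field, b.field)

    def test_aperture_monotonicity_under_gating(self):
        # in-focus energy is proportional to open pupil area, so gating
        # cells off can only reduce it
        cfg = small_config(nz=1)
        mask = np.ones((4, 4), dtype=bool)
        prev = np.inf
        for gate_up_to in (0, 4, 8, 12):
            m = mask.copy()
            m.ravel()[:gate_up_to] = False
            psf = psf_from_pupil(
                make_pupil(cfg, ApertureModulation("grid", grid_mask=m)),
                normalize=False,
            )
            energy = psf.data[0].sum()
            assert energy <= prev + 1e-12
            prev = energy


class TestZernike:
    def test_noll_index_table(self):
        # piston, tilt, defocus, oblique astigmatism
        assert noll_to_nm(1) == (0, 0)
        assert noll_to_nm(2) == (1, 1)
        assert noll_to_nm(4) == (2, 0)
        assert noll_to_nm(5) == (2, -2)

    def test_empty_aberration_is_zero_phase(self):
        rho = np.linspace(0, 1, 32)[None, :]
        assert np.all(zernike_phase(AberrationSpec(), rho, np.zeros_like(rho)) == 0)

    def test_piston_is_constant(self):
        rho = np.random.default_rng(0).random((16, 16))
        phase = zernike_phase(AberrationSpec(((1, 0.3),)), rho, np.zeros_like(rho))
        assert np.allclose(phase, 0.3)

    @pytest.mark.parametrize("noll", [4, 5, 7, 11])
    def test_unit_coefficient_has_unit_rms_over_disc(self, noll):
        cfg = small_config(nx=256, ny=256, nz=2, voxel_xy_nm=150.0)
        pupil = make_pupil(cfg, None, AberrationSpec(((noll, 1.0),)))
        phase = np.angle(pupil.field[pupil.support])
        assert np.sqrt(np.mean(phase**2)) == pytest.approx(1.0, rel=0.02)

    def test_invalid_noll_index_rejected(self):
        with pytest.raises(ValidationError):
            AberrationSpec(((0, 1.0),))


def airy_fwhm_nm(na: float, wavelength_nm: float) -> float:
    """Independent oracle: focal-plane width by direct pupil integration.

    I(r) = | integral_0^a J0(2 pi r rho) rho d rho |^2 with a = NA/lambda,
    evaluated by quadrature; the FWHM is found by bisection.
    """
    a = na / wavelength_nm
    rho = np.linspace(0.0, a, 2000)

    def intensity(r):
        return np.trapezoid(j0(2 * np.pi * r * rho) * rho, rho) ** 2

    half = intensity(0.0) / 2.0
    lo, hi = 0.0, wavelength_nm / na  # bracket: first zero is well beyond FWHM/2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if intensity(mid) > half:
            lo = mid
        else:
            hi = mid
    return 2.0 * lo


class TestPSFFromPupil:
    def test_focal_fwhm_matches_airy_oracle(self):
        cfg = small_config(nx=256, ny=256, nz=4, voxel_xy_nm=65.0)
        psf = psf_from_pupil(make_pupil(cfg))
        cz, cy, _ = psf.center
        measured = fwhm_line(psf, (cz, cy, 0), (cz, cy, cfg.nx - 1), supersample=20)
        assert measured == pytest.approx(airy_fwhm_nm(0.75, 570.0), rel=0.05)

    def test_unaberrated_psf_is_symmetric(self, h_open):
        d = h_open.data
        cz = 16
        for k in (1, 5, 10, 15):
            assert np.allclose(d[cz + k], d[cz - k], rtol=0, atol=1e-6 * d.max())
        # x-y quadrant symmetry at focus (radial symmetry on the square grid)
        focal = d[cz]
        assert np.allclose(focal, np.roll(focal[::-1, :], 1, axis=0),
                           atol=1e-6 * focal.max())
        assert np.allclose(focal, np.roll(focal[:, ::-1], 1, axis=1),
                           atol=1e-6 * focal.max())
        assert np.allclose(focal, focal.T, atol=1e-6 * focal.max())

    def test_in_focus_plane_energy_matches_parseval(self):
        cfg = small_config(nz=1)
        pupil = make_pupil(cfg)
        psf = psf_from_pupil(pupil, normalize=False)
        expected = np.sum(np.abs(pupil.field) ** 2) / (cfg.nx * cfg.ny)
        assert psf.data[0].sum() == pytest.approx(expected, rel=1e-6)

    def test_normalized_psf_sums_to_one(self, h_annular):
        assert h_annular.data.sum() == pytest.approx(1.0, rel=1e-9)
        assert h_annular.normalized

    def test_annular_defocus_energy_forms_ring(self):
        # the annular PSF is a hollow cone: away from focus nearly all
        # slice energy sits off-axis and the radial profile peaks at r > 0
        cfg = small_config(nz=64)
        psf_ann = psf_from_pupil(
            make_pupil(cfg, ApertureModulation("annular", obstruction_ratio=0.8))
        )
        psf_open = psf_from_pupil(make_pupil(cfg))
        dz = 12
        yy, xx = np.indices((64, 64))
        r = np.hypot(yy - 32, xx - 32)
        sl_ann = psf_ann.data[32 + dz]
        sl_open = psf_open.data[32 + dz]
        core_ann = sl_ann[r <= 3].sum() / sl_ann.sum()
        core_open = sl_open[r <= 3].sum() / sl_open.sum()
        assert core_ann < 0.5 * core_open
        rbin = np.round(r).astype(int)
        profile = np.bincount(rbin.ravel(), sl_ann.ravel()) / np.bincount(rbin.ravel())
        assert np.argmax(profile) > 0

    def test_annular_axial_fwhm_exceeds_open(self):
        # depth-of-field extension: the annulus elongates the axial profile
        cfg = small_config(voxel_z_nm=100.0, nz=128)
        open_psf = psf_from_pupil(make_pupil(cfg))
        ann_psf = psf_from_pupil(
            make_pupil(cfg, ApertureModulation("annular", obstruction_ratio=0.8))
        )
        line = ((0, 32, 32), (127, 32, 32))
        assert fwhm_line(ann_psf, *line) > fwhm_line(open_psf, *line)
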