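"""Forward-model tests: vortex phase, pupil construction, PSF symmetries,
normalization and parameter derivatives."""

import numpy as np
import pytest

from vortexfit.optics_model import (
    ConfigurationError,
    EmitterParams,
    OpticalConfig,
    _ModelEval,
    build_pupil,
    image_model,
    model_derivatives,
    psf_fixed,
    psf_free,
    roi_capture_fraction,
    vortex_phase,
    zernike_noll,
)


class TestVortexPhase:
    def test_ramp_origin_and_linearity(self):
        assert vortex_phase(0.0, 1) == 0.0
        beta = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        assert np.allclose(vortex_phase(beta, 1), beta)
        assert np.allclose(vortex_phase(beta, -1), -beta)

    def test_radially_opposing_points_differ_by_pi(self):
        beta = np.linspace(0, np.pi, 20)
        diff = vortex_phase(beta + np.pi, 1) - vortex_phase(beta, 1)
        assert np.allclose(diff, np.pi)

    def test_total_winding_is_2pi(self):
        beta = np.linspace(0, 2 * np.pi, 1000)
        phase = vortex_phase(beta, 1)
        assert np.isclose(phase[-1] - phase[0], 2 * np.pi)

    def test_unsupported_charge(self):
        with pytest.raises(ConfigurationError):
            vortex_phase(0.5, 2)


class TestConfig:
    def test_na_exceeding_immersion_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(na=1.6)

    @pytest.mark.parametrize("kw", [{"roi_size": 14}, {"roi_size": 5},
                                    {"pupil_samples": 16},
                                    {"vortex_charge": 3}])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            OpticalConfig(**kw)


class TestZernike:
    def test_orthonormality_on_disk(self):
        """Coefficients are RMS wavefront: each mode has unit RMS and the
        modes are mutually orthogonal (numeric integration oracle)."""
        n = 601
        g = np.linspace(-1, 1, n)
        xx, yy = np.meshgrid(g, g)
        rho, beta = np.hypot(xx, yy), np.arctan2(yy, xx)
        disk = rho <= 1.0
        modes = [zernike_noll(j, rho, beta)[disk] for j in range(4, 12)]
        for i, zi in enumerate(modes):
            assert np.sqrt(np.mean(zi ** 2)) == pytest.approx(1.0, abs=5e-3)
            for zj in modes[i + 1:]:
                assert abs(np.mean(zi * zj)) < 5e-3

    def test_astigmatism_rms_phase(self):
        """50 mlambda of one mode puts 50/1000*2pi radians RMS into the
        pupil phase (aberration-only, standard PSF)."""
        cfg = OpticalConfig(vortex_charge=0)
        coeffs = np.zeros(12)
        coeffs[1] = 50.0  # Noll 6, vertical astigmatism
        pup = build_pupil(cfg, coeffs)
        phase = pup.phase[pup.mask]
        assert np.sqrt(np.mean(phase ** 2)) == pytest.approx(
            50.0 / 1000.0 * 2 * np.pi, rel=2e-2)


class TestPupil:
    def test_zero_aberration_standard_pupil_has_flat_phase(self):
        pup = build_pupil(OpticalConfig(vortex_charge=0))
        assert np.allclose(pup.phase, 0.0)

    def test_supercritical_zone_geometry(self, config, pupil):
        """SAF zone (complex medium wavevector) exists iff NA > n_medium,
        starting at rho = n_medium/NA."""
        rho = pupil.rho
        evan = np.imag(pupil.kz_medium) > 1e-12
        edge = config.n_medium / config.na
        assert edge == pytest.approx(0.917, abs=1e-3)
        inside = pupil.mask & (rho < edge - 0.02)
        beyond = pupil.mask & (rho > edge + 0.02)
        assert not evan[inside].any()
        assert evan[beyond].all()
        # low-NA water-matched system has no SAF zone
        low = build_pupil(OpticalConfig(na=1.2))
        assert not (np.imag(low.kz_medium)[low.mask] > 1e-12).any()

    def test_wrong_coefficient_count(self, config):
        with pytest.raises(ValueError):
            build_pupil(config, np.zeros(5))


class TestPsfShapes:
    def test_standard_axial_dipole_is_ring(self, standard_config):
        """Without the mask an on-axis dipole gives a ring with a central
        zero (destructive interference)."""
        pup = build_pupil(standard_config)
        img = psf_fixed(EmitterParams(theta=0.0, g2=1.0), pup).mu
        c = img.shape[0] // 2
        # the point zero is smeared by 65-nm pixel integration; the center
        # pixel still sits far below the ring maximum
        assert img[c, c] < 0.1 * img.max()
        assert np.unravel_index(np.argmax(img), img.shape) != (c, c)

    def test_vortex_axial_dipole_is_central_spot(self, pupil):
        """The vortex mask inverts the interference: on-axis dipoles gain
        a bright central spot."""
        img = psf_fixed(EmitterParams(theta=0.0, g2=1.0), pupil).mu
        c = img.shape[0] // 2
        assert img[c, c] == img.max()

    def test_vortex_inplane_dipole_center_dark(self, pupil):
        img = psf_fixed(EmitterParams(theta=90.0, phi=30.0, g2=1.0),
                        pupil).mu
        c = img.shape[0] // 2
        assert img[c, c] < 0.35 * img.max()

    def test_standard_inplane_dipole_peak_at_emitter(self, standard_config):
        pup = build_pupil(standard_config)
        img = psf_fixed(EmitterParams(theta=90.0, phi=45.0, g2=1.0), pup).mu
        c = img.shape[0] // 2
        assert np.unravel_index(np.argmax(img), img.shape) == (c, c)

    @pytest.mark.parametrize("rot", [1, 2, 3])
    def test_rotational_covariance(self, pupil, rot):
        """Rotating the dipole azimuth by multiples of 90 deg rotates the
        unaberrated PSF image by the same angle (exact grid rotation)."""
        base = psf_fixed(EmitterParams(phi=20.0, theta=70.0, g2=1.0),
                         pupil).mu
        rotated = psf_fixed(
            EmitterParams(phi=20.0 + 90.0 * rot, theta=70.0, g2=1.0),
            pupil).mu
        # +90 deg dipole rotation rotates the (row=y, col=x) image by
        # one quadrant in the same sense
        expect = np.rot90(base, k=rot, axes=(1, 0))
        assert np.allclose(rotated, expect, rtol=1e-6, atol=1e-9)

    def test_hemisphere_symmetry(self, pupil):
        """(theta, phi) -> (180-theta, phi+180) is the same dipole."""
        a = psf_fixed(EmitterParams(phi=33.0, theta=55.0, g2=1.0), pupil).mu
        b = psf_fixed(EmitterParams(phi=213.0, theta=125.0, g2=1.0),
                      pupil).mu
        assert np.allclose(a, b, rtol=1e-8)


class TestPsfFree:
    def test_fourfold_symmetry(self, pupil):
        img = psf_free(pupil).mu
        assert np.allclose(img, np.rot90(img), rtol=1e-6, atol=1e-9)

    def test_independent_of_orientation_inputs(self, pupil):
        a = psf_free(pupil, EmitterParams(phi=10.0, theta=20.0)).mu
        b = psf_free(pupil, EmitterParams(phi=130.0, theta=85.0)).mu
        assert np.array_equal(a, b)

    def test_equals_orientation_average(self, pupil, rng):
        """Monte-Carlo average of fixed-dipole PSFs over uniform
        orientations converges to the free-dipole PSF."""
        acc = np.zeros((15, 15))
        n = 600
        for _ in range(n):
            phi = 180.0 * rng.random()
            th = np.degrees(np.arccos(1 - 2 * rng.random()))
            acc += psf_fixed(EmitterParams(phi=phi, theta=th, g2=1.0),
                             pupil).mu
        acc /= n
        free = psf_free(pupil).mu
        bright = free > 0.2 * free.max()
        rel = np.abs(acc[bright] - free[bright]) / free[bright]
        assert np.median(rel) < 0.05


class TestImageModel:
    def test_zero_signal_gives_background(self, config):
        mu = image_model(EmitterParams(n_photons=0.0, background=7.0),
                         config).mu
        assert np.allclose(mu, 7.0)

    def test_g2_limits(self, config, pupil):
        th = EmitterParams(phi=40.0, theta=60.0, g2=1.0, background=0.0,
                           n_photons=1000.0)
        mixed = image_model(th, config, pupil=pupil).mu
        fixed = 1000.0 * psf_fixed(th, pupil).mu / 3.0
        assert np.allclose(mixed, fixed, rtol=1e-9)

    def test_mixture_normalization_parseval(self, rng):
        """The Eq.-style mixture integrates to 1 over the full plane.

        With the image window matched to exactly one alias period of the
        discrete pupil transform, the window sum equals the full-plane
        (Plancherel) integral to numerical precision, for any orientation
        and g2.
        """
        npup, nwin = 32, 95
        cfg = OpticalConfig(pupil_samples=npup, roi_size=nwin,
                            oversampling=1,
                            pixel_size=597.5 * npup / (2 * 1.45 * nwin))
        pup = build_pupil(cfg)
        for _ in range(5):
            th = EmitterParams(phi=180 * rng.random(),
                               theta=180 * rng.random(),
                               g2=rng.random(), background=0.0,
                               n_photons=1.0)
            ev = _ModelEval(pup, th)
            hf, pf = ev.free_density()
            hx, px, _ = ev.fixed_density()
            mix = (1 - th.g2) * hf / pf + th.g2 * hx / px
            total = ev.bin_to_pixels(mix).sum()
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_background_floor_guard(self, config):
        with pytest.raises(FloatingPointError):
            image_model(EmitterParams(n_photons=0.0, background=0.0),
                        config)


class TestCaptureFraction:
    def test_monotone_in_roi_size(self, config):
        vals = [roi_capture_fraction(config.with_(roi_size=r))
                for r in (9, 15, 21, 31, 51)]
        assert np.all(np.diff(vals) > 0)

    def test_large_roi_approaches_unity(self, config):
        # convergence is slow: the supercritical rim puts real energy in
        # a wide halo, but a 99-pixel ROI already holds >90%
        assert roi_capture_fraction(config.with_(roi_size=99)) > 0.9

    def test_mode_override(self, config):
        v = roi_capture_fraction(config, mode="vortex")
        s = roi_capture_fraction(config, mode="standard")
        assert 0 < v < 1 and 0 < s < 1 and not np.isclose(v, s, atol=1e-4)


class TestDerivatives:
    def test_linear_derivatives_exact(self, config, pupil):
        th = EmitterParams(phi=25.0, theta=65.0, g2=0.6)
        mu, jac = model_derivatives(th, config, pupil=pupil)
        assert np.allclose(jac[..., 4], 1.0)
        assert np.allclose(jac[..., 3], (mu - th.background) / th.n_photons)

    @pytest.mark.parametrize("idx,step", [
        (0, 0.1), (1, 0.1), (2, 0.5), (5, 0.02), (6, 0.02), (7, 1e-4)])
    def test_against_central_differences(self, config, pupil, idx, step):
        th = EmitterParams(x=20.0, y=-12.0, z=60.0, phi=25.0, theta=65.0,
                           g2=0.6)
        mu, jac = model_derivatives(th, config, pupil=pupil)

        def mu_at(v):
            return image_model(EmitterParams.from_vector(v), config,
                               pupil=pupil).mu

        v = th.to_vector()
        vp, vm = v.copy(), v.copy()
        vp[idx] += step
        vm[idx] -= step
        fd = (mu_at(vp) - mu_at(vm)) / (2 * step)
        scale = np.max(np.abs(fd))
        assert np.allclose(jac[..., idx], fd, atol=1e-3 * scale)
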