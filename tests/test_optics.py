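"""Phase synthesis, Debye focusing and light-sheet metrology."""

import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.special import j0

from adlsfc import optics as opt
from adlsfc.units import UM
from conftest import fwhm_1d

Z_W = 85 * UM


def focal_intensity(pm, spec, z=0.0):
    return opt.debye_focus(pm, spec, [z]).intensity()[0]


def centroid_x(I, spec):
    n = spec.grid_size
    x = (np.arange(n) - n // 2) * spec.focal_sampling
    return float((I.sum(axis=0) @ x) / I.sum())


class TestBlazedGrating:
    def test_zero_offset_gives_zero_phase(self, spec256):
        pm = opt.blazed_grating_phase(spec256, 0.0, 0.0)
        assert np.all(pm.phase == 0.0)

    def test_shift_theorem_centroid(self, spec256):
        """A 2 um ramp moves the focal centroid by 2 um within half a sample."""
        pm = opt.blazed_grating_phase(spec256, 2.0 * UM, 0.0)
        I = focal_intensity(pm, spec256)
        assert centroid_x(I, spec256) == pytest.approx(
            2.0 * UM, abs=spec256.focal_sampling / 2
        )

    def test_one_sample_shift_is_circular_shift(self, spec256):
        """A ramp of exactly one focal sample reproduces the unshifted
        pattern circularly shifted by one column."""
        flat = focal_intensity(opt.blazed_grating_phase(spec256, 0, 0), spec256)
        shifted = focal_intensity(
            opt.blazed_grating_phase(spec256, spec256.focal_sampling, 0), spec256
        )
        np.testing.assert_allclose(shifted, np.roll(flat, 1, axis=1), atol=1e-10)

    def test_shift_theorem_holds_on_axicon_base(self, spec512_bg, calibrated_axicon):
        """The centroid displacement is independent of the base phase."""
        base = opt.axicon_phase(spec512_bg, calibrated_axicon)
        shifted = base + opt.blazed_grating_phase(spec512_bg, 3.0 * UM, 0.0)
        I0 = opt.debye_focus(base, spec512_bg, [Z_W]).intensity()[0]
        I1 = opt.debye_focus(shifted, spec512_bg, [Z_W]).intensity()[0]
        assert centroid_x(I1, spec512_bg) - centroid_x(I0, spec512_bg) == pytest.approx(
            3.0 * UM, abs=spec512_bg.focal_sampling / 2
        )

    def test_shift_beyond_fov_raises(self, spec256):
        with pytest.raises(ValueError, match="field of view"):
            opt.blazed_grating_phase(spec256, 1.0, 0.0)


class TestAxicon:
    def test_zero_slope_gives_zero_phase(self, spec256):
        assert np.all(opt.axicon_phase(spec256, 0.0).phase == 0.0)

    def test_negative_slope_rejected(self, spec256):
        with pytest.raises(ValueError):
            opt.axicon_phase(spec256, -0.1)

    def test_phase_linear_in_radius(self, spec256):
        """One full 2 pi turn is accumulated at pupil radius lambda/tan(alpha)."""
        tan_alpha = 1e-3
        pm = opt.axicon_phase(spec256, tan_alpha)
        xp, yp = spec256.pupil_coords()
        r = np.hypot(xp, yp)
        r_turn = spec256.wavelength / tan_alpha
        np.testing.assert_allclose(pm.phase, 2 * np.pi * r / r_turn, rtol=1e-12)

    def test_central_lobe_matches_bessel_profile(self, spec512_bg, calibrated_axicon):
        """At the working plane the core is a J0^2 lobe: its FWHM matches
        0.36 lambda / sin(theta_cone) for the local cone angle."""
        w = opt.central_lobe_fwhm(spec512_bg, calibrated_axicon, Z_W)
        ring = (
            spec512_bg.pupil_radius
            * calibrated_axicon
            / spec512_bg.numerical_aperture
            * spec512_bg.refractive_index
        )
        sin_cone = ring / Z_W
        kt = spec512_bg.k * sin_cone
        # J0^2 falls to half at kt*rho = 1.1259 -> FWHM = 2.2518 / kt
        assert w == pytest.approx(2.2518 / kt, rel=0.10)
        assert w == pytest.approx(0.36 * spec512_bg.wavelength / sin_cone, rel=0.12)

    def test_on_axis_beam_is_rotationally_symmetric(self, spec512_bg, calibrated_axicon):
        I = opt.debye_focus(
            opt.axicon_phase(spec512_bg, calibrated_axicon), spec512_bg, [Z_W]
        ).intensity()[0]
        n = spec512_bg.grid_size
        prof_x = I[n // 2, :]
        prof_y = I[:, n // 2]
        np.testing.assert_allclose(prof_x, prof_y, rtol=1e-6, atol=I.max() * 1e-9)


class TestSSPMultiplex:
    def test_single_beam_equals_summed_phases(self, spec256):
        beam = opt.BeamSpec(offset_x=2 * UM, axicon_slope=1e-3)
        pm = opt.ssp_multiplex([beam], spec256)
        ref = opt.beam_phase(spec256, beam)
        np.testing.assert_allclose(pm.phase, ref.phase)

    def test_two_beams_alternate_rows(self, spec256):
        b1 = opt.BeamSpec(offset_x=1 * UM)
        b2 = opt.BeamSpec(offset_x=-1 * UM)
        pm = opt.ssp_multiplex([b1, b2], spec256, stripe_width=1)
        p1 = opt.beam_phase(spec256, b1).phase
        p2 = opt.beam_phase(spec256, b2).phase
        np.testing.assert_allclose(pm.phase[0::2, :], p1[0::2, :])
        np.testing.assert_allclose(pm.phase[1::2, :], p2[1::2, :])

    def test_empty_beam_list_rejected(self, spec256):
        with pytest.raises(ValueError):
            opt.ssp_multiplex([], spec256)

    def test_nine_beams_focus_at_programmed_offsets(self, spec256):
        """Nine stripe-multiplexed beams produce nine maxima at the
        programmed x offsets within one focal sample."""
        s = 3.0 * UM
        beams = opt.sheet_beams(9, s, tan_alpha=0.0)
        pm = opt.ssp_multiplex(beams, spec256)
        I = focal_intensity(pm, spec256)
        n = spec256.grid_size
        prof = I[n // 2 - 2 : n // 2 + 3, :].max(axis=0)
        peaks, _ = find_peaks(prof, height=0.2 * prof.max())
        pos = (peaks - n // 2) * spec256.focal_sampling
        expected = (np.arange(9) - 4) * s
        assert len(pos) == 9
        np.testing.assert_allclose(
            np.sort(pos), expected, atol=spec256.focal_sampling
        )


class TestDebyeFocus:
    def test_zero_amplitude_pupil_gives_zero_field(self, spec256):
        pm = opt.PhaseMap(np.zeros((256, 256)), np.zeros((256, 256)))
        fld = opt.debye_focus(pm, spec256, [0.0, 1 * UM])
        assert np.all(fld.intensity() == 0.0)

    def test_airy_spot_fwhm(self):
        """Flat circular pupil in the scalar limit focuses to an Airy spot
        of FWHM 0.51 lambda / NA."""
        spec = opt.PupilSpec(grid_size=256, apodization="none")
        I = focal_intensity(opt.blazed_grating_phase(spec, 0, 0), spec)
        w = fwhm_1d(I[128, :], spec.focal_sampling)
        assert w == pytest.approx(0.51 * spec.wavelength / 0.4, rel=0.05)

    def test_parseval_energy_conservation(self, spec256):
        pm = opt.blazed_grating_phase(spec256, 1 * UM, 0.5 * UM)
        sin_t, cos_t, kz = spec256.angles()
        P = pm.amplitude * np.exp(1j * pm.phase) * np.sqrt(cos_t) / cos_t
        fld = opt.debye_focus(pm, spec256, [0.0])
        e_pupil = np.sum(np.abs(P) ** 2)
        e_focal = np.sum(fld.intensity()[0])
        assert e_focal == pytest.approx(e_pupil, rel=0.01)

    def test_intensity_z_invariant_without_losses(self, spec512_bg, calibrated_axicon):
        pm = opt.axicon_phase(spec512_bg, calibrated_axicon)
        fld = opt.debye_focus(pm, spec512_bg, [Z_W - 3 * UM, Z_W, Z_W + 3 * UM])
        energies = fld.intensity().sum(axis=(1, 2))
        assert np.ptp(energies) / energies.mean() < 0.01

    def test_scalar_mode_matches_direct_dft(self):
        """64x64 brute-force Fourier sum agrees with the FFT path."""
        spec = opt.PupilSpec(grid_size=64, apodization="none")
        rng = np.random.default_rng(42)
        phase = rng.uniform(0, 2 * np.pi, (64, 64))
        pm = opt.PhaseMap(phase, spec.aperture())
        z = 0.5 * UM
        fld = opt.debye_focus(pm, spec, [z])
        _, _, kz = spec.angles()
        P = pm.amplitude * np.exp(1j * (phase + kz * z))
        i = np.arange(64) - 32
        W = np.exp(2j * np.pi * np.outer(i, i) / 64)  # centred DFT kernel
        direct = W @ P @ W.T / 64.0
        np.testing.assert_allclose(fld.components["x"][0], direct, atol=1e-10)

    def test_empty_z_planes_rejected(self, spec256):
        with pytest.raises(ValueError):
            opt.debye_focus(opt.blazed_grating_phase(spec256, 0, 0), spec256, [])

    def test_vector_mode_intensity_sums_components(self):
        spec = opt.PupilSpec(grid_size=128, polarization="vector_x")
        fld = opt.debye_focus(opt.blazed_grating_phase(spec, 0, 0), spec, [0.0])
        assert set(fld.components) == {"x", "y", "z"}
        I = fld.intensity()
        assert np.all(I >= 0) and I.max() > 0


class TestMeasureSheet:
    def test_gaussian_slab_thickness(self):
        """Analytic slab exp(-y^2 / 2 sigma^2), sigma = 0.34 um ->
        FWHM = 2.355 sigma = 0.80 um."""
        d = 0.05 * UM
        y = (np.arange(200) - 100) * d
        sigma = 0.34 * UM
        I = np.exp(-(y**2) / (2 * sigma**2))
        stack = np.tile(I[None, :, None], (3, 1, 50))
        m = opt.measure_sheet(stack, (1 * UM, d, d))
        assert m.thickness_fwhm == pytest.approx(2.3548 * sigma, rel=0.01)
        assert m.thickness_sd == pytest.approx(0.0, abs=1e-12 * UM)

    def test_uniform_cube_thickness_is_side_length(self):
        d = 0.1 * UM
        stack = np.zeros((3, 100, 20))
        stack[:, 40:60, :] = 1.0  # 20-sample slab = 2 um
        m = opt.measure_sheet(stack, (1 * UM, d, d))
        assert m.thickness_fwhm == pytest.approx(20 * d, abs=d)

    def test_synthetic_nine_lobe_sheet_width(self):
        """Width measured on a sheet built from shifted Bessel lobes equals
        the programmed outer-lobe span within one sample."""
        d = 0.1 * UM
        nx, ny = 256, 64
        x = (np.arange(nx) - nx // 2) * d
        y = (np.arange(ny) - ny // 2) * d
        kt = 2.2518 / (0.8 * UM)
        centers = (np.arange(9) - 4) * 1.5 * UM
        sheet = np.zeros((ny, nx))
        for cx in centers:
            r = np.hypot(y[:, None], x[None, :] - cx)
            lobe = j0(kt * r) ** 2
            lobe[kt * r > 2.4048] = 0.0  # keep the central lobe only
            sheet += lobe
        stack = sheet[None, :, :]
        m = opt.measure_sheet(stack, (1 * UM, d, d))
        # outer lobes reach half max half a lobe-FWHM beyond their centres
        expected = (centers[-1] - centers[0]) + 0.8 * UM
        assert m.width == pytest.approx(expected, abs=2 * d)
        assert m.thickness_fwhm <= m.width

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            opt.measure_sheet(np.zeros((2, 8, 8)), (1e-6, 1e-7, 1e-7))


class TestAntiDiffraction:
    def test_calibrated_lobe_reads_back_target(self, spec512_bg, calibrated_axicon):
        w = opt.central_lobe_fwhm(spec512_bg, calibrated_axicon, Z_W)
        assert w == pytest.approx(0.8 * UM, abs=0.01 * UM)

    def test_bg_beam_outlives_gaussian_focus(self, spec512_bg, calibrated_axicon):
        """Over the z-range in which an equal-waist Gaussian doubles, the
        Bessel-Gaussian core FWHM varies by less than 15%."""
        variation, gauss_factor, widths = opt.anti_diffraction_ratio(
            spec512_bg, calibrated_axicon, Z_W
        )
        assert gauss_factor >= 2.0 - 1e-9
        assert variation < 0.15
        assert np.all(widths > 0)
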