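import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import cumulative_trapezoid

from eprredox.forward import (
    LineshapeModel,
    ScanProtocol,
    absorption_profile,
    acquisition_time,
    double_integral,
    lineshape_profile,
    noise_sd_for_snr,
    plane_projection,
    resolution_estimate,
    simulate_spectra,
)
from eprredox.geometry import golden_mean_directions
from eprredox.phantoms import pillar_phantom
from eprredox.volume import VolumeImage


class TestLineshape:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        width=st.floats(0.01, 0.5),
        shape=st.sampled_from(["lorentzian", "gaussian"]),
    )
    def test_antisymmetric_about_center(self, width, shape):
        ax = np.linspace(-2, 2, 4001)
        prof = lineshape_profile(LineshapeModel(shape, width), ax)
        assert np.allclose(prof, -prof[::-1], atol=1e-10 * np.abs(prof).max())

    @pytest.mark.parametrize("shape", ["lorentzian", "gaussian"])
    def test_peak_to_peak_width_on_dense_grid(self, shape):
        """Extrema separation equals the requested 0.073 mT within a grid step."""
        ax = np.linspace(-1, 1, 200001)
        prof = lineshape_profile(LineshapeModel(shape, 0.073), ax)
        pp = ax[np.argmax(prof)] - ax[np.argmin(prof)]
        assert abs(abs(pp) - 0.073) <= ax[1] - ax[0]

    @pytest.mark.parametrize("shape", ["lorentzian", "gaussian"])
    def test_integral_recovers_absorption(self, shape):
        """Running integral of the derivative is the absorption profile.

        On a finite window the running integral carries the left-tail value
        as its baseline, so the quadrature oracle is the absorption profile
        re-based to zero at the window edge.
        """
        m = LineshapeModel(shape, 0.073)
        ax = np.linspace(-3, 3, 60001)
        prof = lineshape_profile(m, ax)
        absorption = cumulative_trapezoid(prof, ax, initial=0.0)
        ref = absorption_profile(m, ax)
        expected = ref - ref[0]
        assert np.allclose(absorption, expected, atol=1e-6 * ref.max())
        area = cumulative_trapezoid(absorption, ax, initial=0.0)[-1]
        expected_area = cumulative_trapezoid(expected, ax, initial=0.0)[-1]
        assert area == pytest.approx(expected_area, rel=1e-6)

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError):
            lineshape_profile(LineshapeModel(), np.array([0.0, 1.0, 0.5]))


def _brute_force_projection(v, d, field_axis, gradient):
    """Independent plane-binning oracle: per-voxel linear mass split."""
    g_mm = gradient / 1000.0
    db = field_axis[1] - field_axis[0]
    cx, cy, cz = v.coords()
    t = (
        g_mm * d[0] * cx[:, None, None]
        + g_mm * d[1] * cy[None, :, None]
        + g_mm * d[2] * cz[None, None, :]
    )
    u = (t.ravel() - field_axis[0]) / db
    mass = v.data.ravel() * v.voxel_volume * g_mm / db
    j0 = np.floor(u).astype(int)
    w = u - j0
    keep = (j0 >= 0) & (j0 < field_axis.size - 1)
    hist = np.zeros(field_axis.size)
    np.add.at(hist, j0[keep], mass[keep] * (1 - w[keep]))
    np.add.at(hist, j0[keep] + 1, mass[keep] * w[keep])
    return hist


class TestPlaneProjection:
    def test_point_mass_single_peak(self, protocol):
        fa = protocol.field_axis()
        v = VolumeImage(np.zeros((16, 16, 16)), 37.5)
        v.data[11, 4, 8] = 2.5
        d = np.array([0.3, -0.5, 0.8])
        d /= np.linalg.norm(d)
        proj = plane_projection(v, d, fa, 40.0)
        r0 = np.array([v.axis_coords(0)[11], v.axis_coords(1)[4], v.axis_coords(2)[8]])
        expected_b = 0.04 * (r0 @ d)
        peak_b = fa[np.argmax(proj)]
        assert abs(peak_b - expected_b) <= fa[1] - fa[0]

    def test_mass_conservation(self, protocol, ball_volume):
        fa = protocol.field_axis()
        db = fa[1] - fa[0]
        for d in golden_mean_directions(5).vectors:
            proj = plane_projection(ball_volume, d, fa, 40.0)
            lhs = proj.sum() * db
            rhs = ball_volume.data.sum() * ball_volume.voxel_volume * 0.04
            assert lhs == pytest.approx(rhs, rel=5e-3)

    def test_ball_direction_independent_spectra(self, protocol, ball_volume, lineshape):
        """Spectra of a ball are identical for any two directions.

        The comparison is made after lineshape convolution, which resolves
        the sub-voxel binning granularity of the raw histograms.
        """
        ds = golden_mean_directions(3)
        s = simulate_spectra(ball_volume, ds, lineshape, protocol)
        ref = s.spectra[0]
        for row in s.spectra[1:]:
            assert np.abs(row - ref).max() <= 1e-3 * np.abs(ref).max() * 10

    def test_matches_brute_force_oracle(self, protocol):
        fa = protocol.field_axis()
        vol = pillar_phantom(24, 37.5)
        for d in [np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]),
                  golden_mean_directions(3).vectors[2]]:
            ours = plane_projection(vol, d, fa, 40.0)
            oracle = _brute_force_projection(vol, d, fa, 40.0)
            assert np.allclose(ours, oracle, atol=1e-6 * oracle.max())

    def test_out_of_fov_warns(self, protocol):
        v = VolumeImage(np.ones((8, 8, 8)), 80.0)  # 80 mm object in 37.5 mm FOV
        with pytest.warns(RuntimeWarning):
            plane_projection(v, np.array([0, 0, 1.0]), protocol.field_axis(), 40.0)


class TestSimulateSpectra:
    def test_empty_volume_zero_spectra(self, protocol, lineshape):
        v = VolumeImage(np.zeros((8, 8, 8)), 37.5)
        s = simulate_spectra(v, golden_mean_directions(4), lineshape, protocol)
        assert not s.spectra.any()

    def test_point_object_gives_shifted_lineshape(self, lineshape):
        """A point source's spectrum is the shifted, scaled lineshape."""
        p = ScanProtocol(n_field_points=513, includes_zero_gradient=False)
        fa = p.field_axis()
        db = fa[1] - fa[0]
        n = 16
        v = VolumeImage(np.zeros((n, n, n)), 37.5)
        v.data[8, 8, 8] = 1.0
        s = simulate_spectra(v, golden_mean_directions(1), lineshape, p)
        # direct evaluation: projected delta (independent binning oracle)
        # convolved with the derivative lineshape
        oracle = _brute_force_projection(v, s.directions.vectors[0], fa, 40.0)
        kernel_axis = (np.arange(len(fa)) - (len(fa) - 1) // 2) * db
        kernel = lineshape_profile(
            LineshapeModel(lineshape.shape, lineshape.peak_to_peak_width), kernel_axis
        )
        expected = np.convolve(oracle, kernel, mode="same") * db
        assert np.allclose(s.spectra[0], expected, atol=1e-9 * np.abs(expected).max())

    def test_forward_linearity(self, protocol, lineshape, rng):
        ds = golden_mean_directions(4)
        v1 = VolumeImage(rng.random((12, 12, 12)) * 0.2, 20.0)
        v2 = VolumeImage(rng.random((12, 12, 12)) * 0.2, 20.0)
        a, b = 2.0, -0.7
        s1 = simulate_spectra(v1, ds, lineshape, protocol).spectra
        s2 = simulate_spectra(v2, ds, lineshape, protocol).spectra
        s12 = simulate_spectra(
            v1.with_data(a * v1.data + b * v2.data), ds, lineshape, protocol
        ).spectra
        assert np.allclose(s12, a * s1 + b * s2, atol=1e-9 * np.abs(s12).max())

    def test_seeded_noise_reproducible(self, protocol, lineshape, ball_volume):
        ds = golden_mean_directions(3)
        s1 = simulate_spectra(ball_volume, ds, lineshape, protocol, 0.05, seed=42)
        s2 = simulate_spectra(ball_volume, ds, lineshape, protocol, 0.05, seed=42)
        np.testing.assert_array_equal(s1.spectra, s2.spectra)

    def test_subset_is_row_prefix(self, protocol, lineshape, ball_volume):
        s = simulate_spectra(ball_volume, golden_mean_directions(8), lineshape, protocol)
        sub = s.subset(3)
        np.testing.assert_array_equal(sub.spectra, s.spectra[:3])


class TestDoubleIntegral:
    def test_zero_spectrum(self):
        fa = np.linspace(-1, 1, 101)
        assert double_integral(np.zeros(101), fa) == 0.0

    def test_scales_linearly_with_volume(self, protocol, lineshape, ball_volume):
        ds = golden_mean_directions(2)
        s1 = simulate_spectra(ball_volume, ds, lineshape, protocol)
        s2 = simulate_spectra(
            ball_volume.with_data(3.5 * ball_volume.data), ds, lineshape, protocol
        )
        fa = s1.field_axis
        d1 = double_integral(s1.spectra[0], fa)
        d2 = double_integral(s2.spectra[0], fa)
        assert d2 == pytest.approx(3.5 * d1, rel=1e-9)

    def test_recovers_absorption_area(self):
        """Double integration of a derivative Lorentzian returns its area.

        The window spans 80 FWHM linewidths per side: Lorentzian tails decay
        as 1/x^2, so a narrower window truncates more area than the stated
        tolerance allows.
        """
        width = 0.073
        fwhm = np.sqrt(3.0) * width
        fa = np.linspace(-80 * fwhm, 80 * fwhm, 512)
        area_true = 4.2
        spec = area_true * lineshape_profile(LineshapeModel("lorentzian", width), fa)
        assert double_integral(spec, fa) == pytest.approx(area_true, rel=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            double_integral(np.zeros(10), np.linspace(0, 1, 11))


class TestProtocolArithmetic:
    def test_acquisition_time_examples(self):
        p = ScanProtocol(includes_zero_gradient=True)
        assert acquisition_time(256, p) == pytest.approx(33.41)
        assert acquisition_time(128, p) == pytest.approx(16.77)
        p0 = ScanProtocol(includes_zero_gradient=False)
        assert acquisition_time(1, p0) == pytest.approx(0.13)

    def test_resolution_examples(self):
        assert resolution_estimate(0.073, 40.0) == pytest.approx(1.825)
        assert resolution_estimate(0.06, 30.0) == pytest.approx(2.0)
        # dimensional identity: width x, gradient 2x -> half a metre
        assert resolution_estimate(3.7, 7.4) == pytest.approx(500.0)

    def test_fov_convention(self):
        assert ScanProtocol().fov_mm == pytest.approx(37.5)

    def test_noise_sd_for_snr(self):
        spectra = np.array([[0.5, -2.0, 1.0]])
        assert noise_sd_for_snr(spectra, 20.0) == pytest.approx(0.1)
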