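import warnings

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings, strategies as st
from skimage.restoration import denoise_tv_chambolle

from eprredox.cs import (
    ProjectionOperator,
    ReconConfig,
    fista_reconstruct,
    preset,
    renormalize_series,
    soft_threshold,
    total_variation,
    tv_denoise,
)
from eprredox.forward import LineshapeModel, ScanProtocol, simulate_spectra
from eprredox.geometry import golden_mean_directions
from eprredox.phantoms import decay_series, two_compartment_leg_phantom
from eprredox.volume import ImageSeries, VolumeImage


@pytest.fixture(scope="module")
def operator(small_geometry, lineshape):
    g = small_geometry
    return ProjectionOperator(
        g["directions"].vectors,
        g["protocol"].field_axis(),
        g["protocol"].gradient_magnitude,
        g["matrix"],
        g["fov"],
        lineshape,
    )


class TestProjectionOperator:
    def test_adjoint_dot_product(self, operator):
        """<Ax, y> == <x, A^T y> to machine precision."""
        rng = np.random.default_rng(99)
        x = rng.standard_normal(operator.template.data.shape)
        y = rng.standard_normal((operator.n_directions, operator.field_axis.size))
        lhs = np.vdot(operator.forward(x), y)
        rhs = np.vdot(x, operator.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_forward_of_zero_is_zero(self, operator):
        assert not operator.forward(np.zeros(operator.template.data.shape)).any()

    def test_adjoint_of_zero_is_zero(self, operator):
        y = np.zeros((operator.n_directions, operator.field_axis.size))
        assert not operator.adjoint(y).any()

    def test_lipschitz_bounds_operator_norm(self, operator):
        """Power-iteration estimate dominates random Rayleigh quotients."""
        L = operator.lipschitz(seed=0)
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = rng.standard_normal(operator.template.data.shape)
            ratio = (operator.forward(x) ** 2).sum() / (x**2).sum()
            assert ratio <= L * 1.01


class TestSoftThreshold:
    def test_zero_tau_is_identity(self, rng):
        x = rng.standard_normal((4, 4, 4))
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_known_values(self):
        out = soft_threshold(np.array([0.5, -0.1]), 0.2)
        np.testing.assert_allclose(out, [0.3, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(v=st.floats(-5, 5), tau=st.floats(0, 3))
    def test_solves_scalar_prox_problem(self, v, tau):
        """Matches grid search of argmin 1/2 (u - v)^2 + tau |u|."""
        grid = np.linspace(-6, 6, 240001)
        obj = 0.5 * (grid - v) ** 2 + tau * np.abs(grid)
        u_grid = grid[np.argmin(obj)]
        u = soft_threshold(np.array([v]), tau)[0]
        assert abs(u - u_grid) < 1e-4


class TestTvDenoise:
    def test_zero_weight_is_identity(self, rng):
        x = rng.standard_normal((6, 6, 6))
        np.testing.assert_array_equal(tv_denoise(x, 0.0, 10), x)

    def test_constant_volume_unchanged(self):
        x = np.full((6, 6, 6), 3.3)
        np.testing.assert_allclose(tv_denoise(x, 0.5, 20), x, atol=1e-12)

    def test_energy_non_increasing_in_inner_iterations(self, rng):
        x = np.zeros((10, 10, 10))
        x[3:7] = 1.0
        x += rng.normal(0, 0.25, x.shape)
        w = 0.15
        energies = []
        for n_inner in (0, 1, 2, 5, 10, 20, 50):
            u = tv_denoise(x, w, n_inner)
            energies.append(0.5 * ((u - x) ** 2).sum() + w * total_variation(u))
        assert np.all(np.diff(energies) <= 1e-10)

    def test_step_signal_matches_converged_reference(self, rng):
        """Agrees with an independent converged TV solver within 1%."""
        x = np.zeros((4, 4, 32))
        x[:, :, 16:] = 1.0
        x += rng.normal(0, 0.1, x.shape)
        w = 0.05
        ours = tv_denoise(x, w, 50)
        ref = denoise_tv_chambolle(x, weight=w, eps=1e-10, max_num_iter=4000)
        assert np.linalg.norm(ours - ref) / np.linalg.norm(ref) < 0.01
        assert total_variation(ours) <= total_variation(x)


@pytest.fixture(scope="module")
def sparse_points_problem(lineshape):
    protocol = ScanProtocol(includes_zero_gradient=False)
    vol = VolumeImage(np.zeros((24, 24, 24)), 37.5)
    points = [(5, 5, 5), (18, 6, 12), (12, 12, 12), (6, 18, 18), (18, 18, 6)]
    for p in points:
        vol.data[p] = 1.0
    s = simulate_spectra(vol, golden_mean_directions(256), lineshape, protocol)
    return vol, s, points


class TestFistaReconstruct:
    def test_sparse_support_recovery(self, sparse_points_problem, lineshape):
        """Noiseless 5-point source: support and peak positions recovered."""
        vol, s, points = sparse_points_problem
        cfg = ReconConfig(lambda1=1e-4, lambda2=1e-4, n_iter=30, matrix=24, fov=37.5)
        rec = fista_reconstruct(s, cfg, lineshape)
        labels, n_comp = ndi.label(rec.data > 0.3 * rec.data.max())
        assert n_comp == len(points)
        coms = ndi.center_of_mass(rec.data, labels, range(1, n_comp + 1))
        recovered = {tuple(int(round(c)) for c in com) for com in coms}
        assert recovered == set(points)

    def test_enormous_l1_suppresses_everything(self, sparse_points_problem, lineshape):
        vol, s, _ = sparse_points_problem
        cfg = ReconConfig(lambda1=1e9, lambda2=0.0, n_iter=4, matrix=24, fov=37.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rec = fista_reconstruct(s, cfg, lineshape)
        assert not rec.data.any()

    def test_objective_non_increasing_four_iterations(
        self, sparse_points_problem, lineshape
    ):
        """The monotone FISTA objective never increases over the 4 iterations."""
        vol, s, _ = sparse_points_problem
        cfg = preset("phantom", matrix=24, fov=37.5, n_iter=4)
        _, info = fista_reconstruct(s, cfg, lineshape, return_info=True)
        obj = np.asarray(info["objective"])
        assert obj.size == 5
        assert np.all(np.diff(obj) <= 1e-12)

    def test_zero_observations_give_zero_volume(self, lineshape):
        protocol = ScanProtocol(includes_zero_gradient=False)
        v = VolumeImage(np.zeros((8, 8, 8)), 37.5)
        s = simulate_spectra(v, golden_mean_directions(8), lineshape, protocol)
        with pytest.warns(RuntimeWarning):
            rec = fista_reconstruct(
                s, ReconConfig(matrix=8, fov=37.5), lineshape
            )
        assert not rec.data.any()

    def test_unregularized_limit_matches_least_squares(self, lineshape):
        """With no penalties and many iterations, FISTA reaches the LS fit."""
        rng = np.random.default_rng(5)
        protocol = ScanProtocol(n_field_points=48, includes_zero_gradient=False)
        ds = golden_mean_directions(24)
        vol = VolumeImage(np.zeros((8, 8, 8)), 37.5)
        cx, cy, cz = vol.coords()
        inside = (
            cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
        ) < 15.0**2
        vol.data[inside] = rng.random(int(inside.sum()))
        s = simulate_spectra(vol, ds, lineshape, protocol)
        scale = np.max(np.abs(s.spectra))

        op = ProjectionOperator(
            ds.vectors, protocol.field_axis(), 40.0, 8, 37.5, lineshape
        )
        A = np.zeros((24 * 48, 512))
        for j in range(512):
            e = np.zeros(512)
            e[j] = 1.0
            A[:, j] = op.forward(e.reshape(8, 8, 8)).ravel()
        y = s.spectra.ravel() / scale
        x_ls, *_ = np.linalg.lstsq(A, y, rcond=None)
        res_ls = np.linalg.norm(A @ x_ls - y)

        cfg = ReconConfig(
            lambda1=0.0, lambda2=0.0, n_iter=300, matrix=8, fov=37.5, nonneg=False
        )
        _, info = fista_reconstruct(s, cfg, lineshape, return_info=True)
        res_fista = np.sqrt(2.0 * info["objective"][-1])
        assert res_fista <= max(1.05 * res_ls, 0.05 * np.linalg.norm(y))


class TestRenormalizeSeries:
    def _series_and_spectra(self, lineshape, scale_second=1.0, noiseless=True):
        protocol = ScanProtocol(includes_zero_gradient=False)
        ds = golden_mean_directions(6)
        base = VolumeImage(np.zeros((12, 12, 12)), 37.5)
        base.data[4:8, 4:8, 4:8] = 1.0
        frames = [base, base.with_data(base.data.copy())]
        spectra = [
            simulate_spectra(base, ds, lineshape, protocol),
            simulate_spectra(
                base.with_data(scale_second * base.data), ds, lineshape, protocol
            ),
        ]
        series = ImageSeries(frames, np.array([0.0, 10.0]))
        return series, spectra

    def test_factor_two_spectra_scale_frames(self, lineshape):
        series, spectra = self._series_and_spectra(lineshape, scale_second=2.0)
        out = renormalize_series(series, spectra)
        ratio = out.frames[1].data[5, 5, 5] / out.frames[0].data[5, 5, 5]
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_single_frame_proportional(self, lineshape):
        series, spectra = self._series_and_spectra(lineshape)
        one = ImageSeries([series.frames[0]], np.array([0.0]))
        out = renormalize_series(one, [spectra[0]])
        ratio = out.frames[0].data[series.frames[0].data > 0] / series.frames[0].data[
            series.frames[0].data > 0
        ]
        assert np.allclose(ratio, ratio.flat[0])

    def test_count_mismatch_rejected(self, lineshape):
        series, spectra = self._series_and_spectra(lineshape)
        with pytest.raises(ValueError):
            renormalize_series(series, spectra[:1])

    def test_uniform_decay_ratio_recovered(self, lineshape):
        """Noiseless uniform decay: frame-mean ratios follow exp(-k dt)."""
        k = 0.71  # 1/min
        times = np.array([30.0, 60.0, 90.0])
        spec = two_compartment_leg_phantom(
            16, rate_normal=k, rate_tumor=k, frame_times=times
        )
        truth = decay_series(spec)
        protocol = ScanProtocol(includes_zero_gradient=False)
        ds = golden_mean_directions(6)
        spectra = [
            simulate_spectra(f, ds, lineshape, protocol) for f in truth.frames
        ]
        # per-frame max-normalized volumes stand in for CS reconstructions
        frames = [f.with_data(f.data / f.data.max()) for f in truth.frames]
        out = renormalize_series(ImageSeries(frames, times), spectra)
        means = [f.data.mean() for f in out.frames]
        for i in range(1, 3):
            expected = np.exp(-k * (times[i] - times[0]) / 60.0)
            assert means[i] / means[0] == pytest.approx(expected, rel=0.02)
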