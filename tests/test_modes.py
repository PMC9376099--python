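"""Complex SVD modes, responsive-mode selection, gradients and kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavepipe.containers import GridGeometry
from wavepipe.modes import (
    complex_svd,
    phase_gradient,
    reconstruct_mode,
    select_responsive_mode,
    spatial_phase_offset,
    wave_kinematics,
)


def _random_complex(rng, n, t):
    return rng.standard_normal((n, t)) + 1j * rng.standard_normal((n, t))


def _planar_column(geometry, direction, lam):
    d = np.asarray(direction, dtype=float)
    k = 2 * np.pi / lam
    return np.exp(-1j * k * (geometry.positions @ d))


class TestComplexSvd:
    def test_rank_one_wave_concentrates_in_mode_one(self, geometry):
        u = _planar_column(geometry, (0.0, 1.0), 12.5)
        v = np.exp(1j * 2 * np.pi * 4.5 * np.arange(500) / 1000.0)
        modes = complex_svd(np.outer(u, v))
        assert modes.variance_fractions[0] >= 0.999

    def test_reconstruction_identity(self, rng):
        A = _random_complex(rng, 20, 80)
        modes = complex_svd(A)
        rel = np.linalg.norm(A - modes.reconstruct()) / np.linalg.norm(A)
        assert rel < 1e-10

    def test_unitary_factors(self, rng):
        modes = complex_svd(_random_complex(rng, 12, 40))
        np.testing.assert_allclose(modes.U.conj().T @ modes.U,
                                   np.eye(12), atol=1e-10)
        np.testing.assert_allclose(modes.Vh @ modes.Vh.conj().T,
                                   np.eye(12), atol=1e-10)

    def test_variance_fractions_sum_to_one(self, rng):
        modes = complex_svd(_random_complex(rng, 8, 30))
        assert np.isclose(modes.variance_fractions.sum(), 1.0)

    def test_rejects_non_finite(self):
        A = np.zeros((4, 10), dtype=complex)
        A[0, 0] = np.nan
        with pytest.raises(ValueError):
            complex_svd(A)


class TestModeSelection:
    def _modes_with_burst(self, rng, n=20, t=700, burst_mode=0):
        """Orthonormal factors where one mode's temporal amplitude steps up
        post-stimulus."""
        t_axis = (np.arange(t) - 300) / 1000.0
        q, _ = np.linalg.qr(_random_complex(rng, n, n))
        v = _random_complex(rng, n, t)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        amp = np.ones(t) + 0.05 * rng.standard_normal(t)
        amp[t_axis >= 0] += 4.0
        v[burst_mode] *= amp
        s = np.linspace(2.0, 1.0, n)
        A = (q * s) @ v
        return complex_svd(A), t_axis

    def test_single_mode_amplitude_step_selects_first(self):
        t_axis = (np.arange(700) - 300) / 1000.0
        amp = np.where(t_axis >= 0, 5.0, 1.0) + 0.01 * np.sin(977 * t_axis)
        A = np.outer(np.exp(1j * np.linspace(0, 1, 6)),
                     amp * np.exp(1j * 2 * np.pi * 40 * t_axis))
        sel = select_responsive_mode(complex_svd(A), t_axis,
                                     pre_window=0.3, post_window=0.35)
        assert sel.index == 0 and sel.responsive

    def test_burst_mode_recovered(self, rng):
        modes, t_axis = self._modes_with_burst(rng, burst_mode=3)
        sel = select_responsive_mode(modes, t_axis, pre_window=0.3,
                                     post_window=0.35)
        w_t_selected = modes.temporal_amplitude(sel.index)
        post = t_axis >= 0
        ratio = w_t_selected[post].mean() / w_t_selected[~post].mean()
        assert ratio > 2.0 and sel.responsive

    def test_stationary_noise_flagged_non_responsive(self, rng):
        A = _random_complex(rng, 10, 600)
        t_axis = (np.arange(600) - 300) / 1000.0
        sel = select_responsive_mode(complex_svd(A), t_axis, pre_window=0.3,
                                     post_window=0.3)
        assert not sel.responsive

    def test_selected_spatial_phase_matches_ground_truth(
        self, geometry, slow_wave_ensemble
    ):
        """The selected mode's spatial phase circularly correlates with the
        generator's planar phase profile."""
        from wavepipe.timefreq import analytic_signal, butterworth_band

        ens = slow_wave_ensemble
        x = butterworth_band(ens.lfp[0], (3.0, 6.0), ens.sampling_rate)
        modes = complex_svd(analytic_signal(x))
        sel = select_responsive_mode(modes, ens.t_axis, post_window=1.0)
        theta = modes.spatial_phase(sel.index)
        truth = -2 * np.pi * (geometry.positions @ np.array([0.0, 1.0])) / 12.5
        # circular correlation via resultant of phase differences
        r = np.abs(np.exp(1j * (theta - truth)).mean())
        assert r > 0.9


class TestSpatialPhaseOffset:
    def test_planar_wave_offsets_grow_linearly(self, geometry):
        lam = 12.5
        u = _planar_column(geometry, (0.0, 1.0), lam)
        ref = geometry.nearest_channel(1.0, -3.0)
        off = spatial_phase_offset(u, ref)
        assert off[ref] == 0.0
        ap = geometry.positions[:, 1] - geometry.positions[ref, 1]
        expected = np.angle(np.exp(-1j * 2 * np.pi * ap / lam))
        np.testing.assert_allclose(off, expected, atol=1e-9)

    def test_uniform_mode_all_zero(self):
        off = spatial_phase_offset(np.full(10, 1 + 1j), 4)
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    @given(phi=st.floats(-np.pi, np.pi))
    @settings(max_examples=25, deadline=None)
    def test_gauge_invariance(self, phi):
        rng = np.random.default_rng(7)
        u = np.exp(1j * rng.uniform(-np.pi, np.pi, 12))
        base = spatial_phase_offset(u, 3)
        rot = spatial_phase_offset(u * np.exp(1j * phi), 3)
        np.testing.assert_allclose(np.angle(np.exp(1j * (base - rot))), 0.0,
                                   atol=1e-9)


class TestPhaseGradient:
    def test_conjugate_product_identity(self):
        z1, z2 = np.exp(1j * 0.7), np.exp(1j * 0.2)
        assert np.isclose(np.angle(z1 * np.conj(z2)), 0.5)

    @pytest.mark.parametrize("alpha_deg", [0.0, 45.0, 90.0, 135.0, 210.0])
    def test_planar_wave_norm_and_direction(self, geometry, alpha_deg):
        lam = 12.5
        alpha = np.radians(alpha_deg)
        u = _planar_column(geometry, (np.cos(alpha), np.sin(alpha)), lam)
        gf = phase_gradient(u, geometry)
        interior = [
            geometry.as_grid_index()[r, c]
            for r in range(1, geometry.n_rows - 1)
            for c in range(1, geometry.n_cols - 1)
        ]
        np.testing.assert_allclose(gf.norm[interior], 2 * np.pi / lam,
                                   rtol=0.02)
        ang_err = np.degrees(
            np.abs(np.angle(np.exp(1j * (gf.direction[interior] - alpha))))
        )
        assert ang_err.max() < 5.0

    def test_uniform_mode_zero_gradient(self, geometry):
        gf = phase_gradient(np.ones(geometry.n_channels, dtype=complex),
                            geometry)
        assert np.nanmax(gf.norm) < 1e-8

    def test_missing_channel_propagates_nan(self, geometry):
        u = _planar_column(geometry, (0.0, 1.0), 12.5)
        u[geometry.as_grid_index()[5, 3]] = np.nan
        gf = phase_gradient(u, geometry)
        # the dead site has no estimate; its neighbors lose one side only
        assert np.isnan(gf.grad[geometry.as_grid_index()[5, 3]]).all()
        assert np.isfinite(gf.grad[geometry.as_grid_index()[5, 1]]).all()


class TestKinematics:
    def test_wavelength_arithmetic(self, geometry):
        u = _planar_column(geometry, (1.0, 0.0), 4 * np.pi)  # grad 0.5 rad/mm
        gf = phase_gradient(u, geometry)
        t_axis = np.arange(500) / 1000.0
        theta_t = 2 * np.pi * 4.5 * t_axis
        kin = wave_kinematics(gf, theta_t, t_axis)
        interior = geometry.as_grid_index()[5, 3]
        assert np.isclose(kin.wavelength_mm[interior], 4 * np.pi, rtol=1e-6)

    @pytest.mark.parametrize("freq,lam", [(40.0, 12.7), (4.5, 12.5)])
    def test_velocity_equals_frequency_times_wavelength(self, geometry,
                                                        freq, lam):
        u = _planar_column(geometry, (0.0, 1.0), lam)
        gf = phase_gradient(u, geometry)
        t_axis = np.arange(1000) / 1000.0
        kin = wave_kinematics(gf, 2 * np.pi * freq * t_axis, t_axis)
        ok = np.isfinite(kin.velocity_mm_s)
        np.testing.assert_allclose(
            kin.velocity_mm_s[ok], kin.f_t_hz * kin.wavelength_mm[ok],
            rtol=1e-9,
        )
        assert np.isclose(np.nanmedian(kin.velocity_mm_s), freq * lam,
                          rtol=0.02)

    def test_zero_gradient_undefined_not_infinite(self, geometry):
        gf = phase_gradient(np.ones(geometry.n_channels, dtype=complex),
                            geometry)
        t_axis = np.arange(300) / 1000.0
        kin = wave_kinematics(gf, 2 * np.pi * 4.5 * t_axis, t_axis)
        assert np.isnan(kin.wavelength_mm).all()
        assert np.isnan(kin.velocity_mm_s).all()

    @given(phi=st.floats(-np.pi, np.pi))
    @settings(max_examples=10, deadline=None)
    def test_gauge_invariance_of_kinematics(self, phi):
        geometry = GridGeometry.rectangular()
        u = _planar_column(geometry, (0.0, 1.0), 12.5)
        a = phase_gradient(u, geometry)
        b = phase_gradient(u * np.exp(1j * phi), geometry)
        np.testing.assert_allclose(a.grad, b.grad, atol=1e-9)


class TestReconstruction:
    def test_sum_over_modes_recovers_real_part(self, rng):
        A = _random_complex(rng, 8, 30)
        modes = complex_svd(A)
        total = sum(reconstruct_mode(modes, i) for i in range(modes.n_modes))
        np.testing.assert_allclose(total, np.real(A), atol=1e-9)

    def test_rank_one_input_single_mode(self, rng):
        A = np.outer(_random_complex(rng, 8, 1).ravel(),
                     _random_complex(rng, 30, 1).ravel())
        modes = complex_svd(A)
        np.testing.assert_allclose(reconstruct_mode(modes, 0), np.real(A),
                                   atol=1e-9)

    def test_zero_singular_value_mode_is_zero(self, rng):
        A = np.outer(_random_complex(rng, 8, 1).ravel(),
                     _random_complex(rng, 30, 1).ravel())
        modes = complex_svd(A)
        assert np.allclose(reconstruct_mode(modes, 5), 0.0, atol=1e-12)
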