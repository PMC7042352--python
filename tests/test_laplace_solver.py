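import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dplskin import (DegenerateRootsError, DimensionlessParams, DomainError,
                     LoadingSpec, SingularCoefficientError,
                     boundary_amplitudes, characteristic_roots,
                     field_transforms, solve_field_transforms,
                     transform_coefficients)
from dplskin.laplace_solver import TransformCoefficients, strain_mode_weights


def _tc(ell, m):
    """Minimal coefficient record for root-only tests."""
    z = np.atleast_1d(np.asarray(ell, dtype=complex))
    return TransformCoefficients(s=np.ones_like(z), a1=np.ones_like(z),
                                 a2=np.ones_like(z), Q_tilde=np.zeros_like(z),
                                 ell=z, m=np.atleast_1d(np.asarray(m, dtype=complex)))


class TestTransformCoefficients:
    def test_equal_lags_cancel(self):
        p = DimensionlessParams(tau_q=0.03, tau_T=0.03, beta1=0.5)
        tc = transform_coefficients(1.0, p)
        assert tc.a1[0] == pytest.approx(1.5)

    def test_unequal_lag_formula_arithmetic(self):
        p = DimensionlessParams(tau_q=0.02, tau_T=0.04, beta1=0.5)
        tc = transform_coefficients(1.0, p)
        assert tc.a1[0] == pytest.approx(1.02 * 1.5 / 1.04, rel=1e-12)

    def test_zero_source_gives_zero_q_tilde(self):
        p = DimensionlessParams(Q=0.0)
        tc = transform_coefficients(np.array([1.0 + 2.0j, 5.0]), p)
        assert np.all(tc.Q_tilde == 0)

    def test_invariant_identities(self, params, contour_points):
        tc = transform_coefficients(contour_points, params)
        np.testing.assert_allclose(tc.ell, tc.a1 + tc.s ** 2 + tc.a2 * params.beta3)
        np.testing.assert_allclose(tc.m, tc.a1 * tc.s ** 2)

    def test_pole_raises(self, params):
        with pytest.raises(SingularCoefficientError):
            transform_coefficients(0.0, params)
        with pytest.raises(SingularCoefficientError):
            transform_coefficients(-1.0 / params.tau_T, params)


class TestCharacteristicRoots:
    def test_factored_quartic(self):
        k1, k2 = characteristic_roots(_tc(5.0, 4.0))
        assert k1[0] == pytest.approx(1.0) and k2[0] == pytest.approx(2.0)

    def test_double_root(self):
        k1, k2 = characteristic_roots(_tc(2.0, 1.0))
        assert k1[0] == pytest.approx(1.0) and k2[0] == pytest.approx(1.0)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateRootsError):
            characteristic_roots(_tc(0.0, 0.0))

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(*[st.floats(-50, 50) for _ in range(4)]))
    def test_roots_match_general_quartic_solver(self, vals):
        """Root pairs agree (as sets) with numpy's polynomial root finder."""
        ell = complex(vals[0], vals[1])
        m = complex(vals[2], vals[3])
        if abs(ell) < 1e-6 and abs(m) < 1e-6:
            return
        k1, k2 = characteristic_roots(_tc(ell, m))
        assert k1[0].real >= 0 and k2[0].real >= 0
        assert abs(k1[0]) <= abs(k2[0]) + 1e-12
        ours = [k1[0] ** 2, k2[0] ** 2]
        ref = list(np.roots([1.0, -ell, m]))
        scale = max(1.0, abs(ell), abs(m) ** 0.5)
        # match as sets: take the pairing with the smaller total distance
        straight = abs(ours[0] - ref[0]) + abs(ours[1] - ref[1])
        crossed = abs(ours[0] - ref[1]) + abs(ours[1] - ref[0])
        assert min(straight, crossed) < 1e-8 * scale ** 2

    def test_vieta_on_contour(self, params, contour_points):
        tc = transform_coefficients(contour_points, params)
        k1, k2 = characteristic_roots(tc)
        np.testing.assert_allclose(k1 ** 2 + k2 ** 2, tc.ell, rtol=1e-10)
        np.testing.assert_allclose(k1 ** 2 * k2 ** 2, tc.m, rtol=1e-10)


class TestBoundaryAmplitudes:
    def test_zero_data_gives_zero_amplitudes(self, contour_points):
        p = DimensionlessParams(Q=0.0)
        tc = transform_coefficients(contour_points, p)
        roots = characteristic_roots(tc)
        mc = boundary_amplitudes(tc, roots, np.zeros_like(contour_points), p)
        for a in (mc.eps1, mc.eps2, mc.eta1_c, mc.eta2_c):
            np.testing.assert_allclose(a, 0.0, atol=1e-30)

    def test_boundary_equations_satisfied(self, params, contour_points):
        load = LoadingSpec("ramp", t0=0.05)
        g_bar = load.transform(contour_points)
        tc = transform_coefficients(contour_points, params)
        k1, k2 = characteristic_roots(tc)
        mc = boundary_amplitudes(tc, (k1, k2), g_bar, params)
        e1, e2 = np.exp(-k1 * params.L), np.exp(-k2 * params.L)
        # theta(0) = g_bar:  sum(eps_i + eta_i) = alpha1
        lhs = mc.eps1 + mc.eps2 + mc.eta1_c * e1 + mc.eta2_c * e2
        np.testing.assert_allclose(lhs, mc.alpha1, rtol=1e-8, atol=1e-12)
        # e(L) = 0:  sum (k_i^2 - a1)(eps_i e^{-k_i L} + eta_i e^{k_i L}) = 0
        d1, d2 = strain_mode_weights(tc, (k1, k2), params)
        lhs = d1 * (mc.eps1 * e1 + mc.eta1_c) + d2 * (mc.eps2 * e2 + mc.eta2_c)
        scale = np.maximum(np.abs(d1 * mc.alpha1), 1e-30)
        np.testing.assert_allclose(lhs / scale, 0.0, atol=1e-6)

    def test_solution_matches_cramer_oracle(self, params, contour_points):
        """Independent Cramer's-rule solve of the same 4x4 system."""
        load = LoadingSpec("thermal_shock", nu=0.02)
        g_bar = load.transform(contour_points)
        tc = transform_coefficients(contour_points, params)
        k1, k2 = characteristic_roots(tc)
        mc = boundary_amplitudes(tc, (k1, k2), g_bar, params)
        d1_all, d2_all = strain_mode_weights(tc, (k1, k2), params)
        for i in range(0, contour_points.size, 7):
            e1, e2 = np.exp(-k1[i] * params.L), np.exp(-k2[i] * params.L)
            d1, d2 = d1_all[i], d2_all[i]
            mat = np.array([[1, 1, e1, e2],
                            [e1, e2, 1, 1],
                            [d1, d2, d1 * e1, d2 * e2],
                            [d1 * e1, d2 * e2, d1, d2]])
            rhs = np.array([mc.alpha1[i], -tc.Q_tilde[i] / tc.a1[i],
                            tc.a2[i] * mc.alpha2[i], 0.0])
            det = np.linalg.det(mat)
            got = np.array([mc.eps1[i], mc.eps2[i], mc.eta1_c[i], mc.eta2_c[i]])
            for col in range(4):
                m_col = mat.copy()
                m_col[:, col] = rhs
                expected = np.linalg.det(m_col) / det
                assert got[col] == pytest.approx(expected, rel=1e-6, abs=1e-18)


class TestFieldTransforms:
    @pytest.fixture
    def solved(self, params, contour_points):
        load = LoadingSpec("ramp", t0=0.07)
        g_bar = load.transform(contour_points)
        tc = transform_coefficients(contour_points, params)
        roots = characteristic_roots(tc)
        mc = boundary_amplitudes(tc, roots, g_bar, params)
        return tc, mc, g_bar

    def test_boundary_identities(self, params, solved):
        tc, mc, g_bar = solved
        theta0, e0, sigma0, _ = field_transforms(0.0, mc, tc, params)
        np.testing.assert_allclose(theta0, g_bar, rtol=1e-8, atol=1e-14)
        np.testing.assert_allclose(e0, params.beta3 * g_bar, rtol=1e-6, atol=1e-14)
        np.testing.assert_allclose(sigma0, 0.0, atol=1e-12)
        thetaL, eL, sigmaL, _ = field_transforms(params.L, mc, tc, params)
        np.testing.assert_allclose(thetaL, 0.0, atol=1e-12)
        np.testing.assert_allclose(eL, 0.0, atol=1e-12)
        np.testing.assert_allclose(sigmaL, 0.0, atol=1e-12)

    def test_ode_residuals(self, params, solved):
        """The transforms satisfy the coupled Laplace-domain ODEs pointwise."""
        tc, mc, _ = solved
        rng = np.random.default_rng(7)
        x = rng.uniform(0.0, params.L, size=9)
        theta, e_bar, _, _ = field_transforms(x, mc, tc, params)
        # analytic second derivatives from the exponential modes
        sl = (slice(None), None)
        d2_theta = np.zeros_like(theta)
        d2_e = np.zeros_like(e_bar)
        weights = strain_mode_weights(tc, (mc.k1, mc.k2), params)
        for (k, eps, eta), d_i in zip(
                ((mc.k1, mc.eps1, mc.eta1_c), (mc.k2, mc.eps2, mc.eta2_c)), weights):
            term = eps[sl] * np.exp(-k[sl] * x) + eta[sl] * np.exp(-k[sl] * (params.L - x))
            d2_theta += k[sl] ** 2 * term
            d2_e += k[sl] ** 2 * d_i[sl] * term / tc.a2[sl]
        res1 = d2_theta - tc.a1[sl] * theta - tc.a2[sl] * e_bar + tc.Q_tilde[sl]
        res2 = d2_e - tc.s[sl] ** 2 * e_bar - params.beta3 * d2_theta
        scale1 = np.maximum(np.abs(d2_theta), 1.0)
        scale2 = np.maximum(np.abs(d2_e), 1.0)
        assert np.max(np.abs(res1) / scale1) < 1e-8
        assert np.max(np.abs(res2) / scale2) < 1e-8

    def test_quartic_elimination_identity(self, params, solved):
        """[D^4 - ell*D^2 + m] theta_bar = s^2 * Q~ holds pointwise."""
        tc, mc, _ = solved
        x = np.array([0.04, 0.11, 0.26])
        sl = (slice(None), None)
        theta, _, _, _ = field_transforms(x, mc, tc, params)
        d2 = np.zeros_like(theta)
        d4 = np.zeros_like(theta)
        for k, eps, eta in ((mc.k1, mc.eps1, mc.eta1_c), (mc.k2, mc.eps2, mc.eta2_c)):
            term = eps[sl] * np.exp(-k[sl] * x) + eta[sl] * np.exp(-k[sl] * (params.L - x))
            d2 += k[sl] ** 2 * term
            d4 += k[sl] ** 4 * term
        lhs = d4 - tc.ell[sl] * d2 + tc.m[sl] * theta
        rhs = np.broadcast_to(tc.s[sl] ** 2 * tc.Q_tilde[sl], lhs.shape)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-7, atol=1e-10)

    def test_displacement_derivative_recovers_strain(self, params, solved):
        """Centered differences of u_bar reproduce e_bar to O(h^2)."""
        tc, mc, _ = solved
        h = 1e-5
        x = np.array([0.05, 0.15, 0.25])
        _, e_bar, _, _ = field_transforms(x, mc, tc, params)
        _, _, _, u_plus = field_transforms(x + h, mc, tc, params)
        _, _, _, u_minus = field_transforms(x - h, mc, tc, params)
        du = (u_plus - u_minus) / (2 * h)
        np.testing.assert_allclose(du, e_bar, rtol=1e-4, atol=1e-12)

    def test_x_outside_domain_rejected(self, params, solved):
        tc, mc, _ = solved
        with pytest.raises(DomainError):
            field_transforms(params.L + 0.01, mc, tc, params)


class TestDecoupledBranch:
    def test_continuous_limit_as_beta2_vanishes(self, params, contour_points):
        """The beta2=0 branch is the limit of the coupled solve."""
        s = contour_points[:16]
        load = LoadingSpec("ramp", t0=0.05)
        g = load.transform(s)
        x = np.array([0.0, 0.1, 0.2, 0.3])
        p_small = dataclasses.replace(params, beta2=1e-9)
        p_zero = dataclasses.replace(params, beta2=0.0)
        coupled = solve_field_transforms(s, p_small, g, x)
        decoupled = solve_field_transforms(s, p_zero, g, x)
        for a, b in zip(coupled, decoupled):
            np.testing.assert_allclose(a, b, rtol=1e-4, atol=1e-14)

    def test_decoupled_boundary_identities(self, params, contour_points):
        p_zero = dataclasses.replace(params, beta2=0.0)
        g = LoadingSpec("thermal_shock", nu=0.0).transform(contour_points)
        theta, e_bar, sigma, _ = solve_field_transforms(
            contour_points, p_zero, g, np.array([0.0, p_zero.L]))
        np.testing.assert_allclose(theta[:, 0], g, rtol=1e-9)
        np.testing.assert_allclose(e_bar[:, 0], p_zero.beta3 * g, rtol=1e-9)
        np.testing.assert_allclose(theta[:, 1], 0.0, atol=1e-13)
        np.testing.assert_allclose(sigma[:, 1], 0.0, atol=1e-13)
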