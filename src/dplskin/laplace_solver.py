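"""Closed-form Laplace-domain solution of the coupled thermoelastic system.

In the Laplace domain the dimensionless dual-phase-lag energy equation and the
motion equation reduce, after eliminating one field, to the quartic operator
``D**4 - ell*D**2 + m`` acting on either the temperature increment
``theta_bar`` or the strain ``e_bar``, with

    a1 = (1 + tau_q*s)*(s + beta1)/(1 + tau_T*s)
    a2 = (1 + tau_q*s)*beta2/(1 + tau_T*s)
    Q~ = Q / (s*(1 + tau_T*s))
    ell = a1 + s**2 + a2*beta3,     m = a1*s**2.

The general solution is a sum of two exponential modes ``exp(-k_i*x)`` /
``exp(+k_i*x)`` where ``+-k_1, +-k_2`` are the quartic roots, plus the
particular term ``Q~/a1`` in the temperature.  The four mode amplitudes
``eps_1, eps_2, eta_1, eta_2`` follow from the boundary conditions
``theta_bar(0)=g_bar``, ``theta_bar(L)=0`` and the traction-free conditions
``sigma_bar(0)=sigma_bar(L)=0`` (equivalently ``e_bar(0)=beta3*g_bar``,
``e_bar(L)=0``) via a 4x4 linear system.

Numerical conditioning: the growing-mode amplitudes are stored rescaled, as
coefficients of ``exp(-k_i*(L-x))`` rather than of ``exp(+k_i*x)``, so that
every matrix entry and basis function is bounded by one in modulus on the
inversion contour; the solved system is algebraically equivalent.  All
operations are vectorised over arrays of contour points ``s``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_params import DimensionlessParams
from .errors import (DegenerateRootsError, DomainError, SingularCoefficientError,
                     SingularSystemError)

__all__ = [
    "TransformCoefficients",
    "ModeCoefficients",
    "transform_coefficients",
    "characteristic_roots",
    "boundary_amplitudes",
    "strain_mode_weights",
    "field_transforms",
    "solve_field_transforms",
]

#: residual threshold (relative) above which the boundary solve is rejected
_RESIDUAL_TOL = 1e-6


@dataclass(frozen=True)
class TransformCoefficients:
    """Per-s coefficients of the Laplace-domain system (arrays over contour points)."""

    s: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    Q_tilde: np.ndarray
    ell: np.ndarray
    m: np.ndarray


@dataclass(frozen=True)
class ModeCoefficients:
    """Roots and mode amplitudes of the Laplace-domain solution.

    ``eps1``/``eps2`` multiply the decaying basis ``exp(-k_i*x)``;
    ``eta1_c``/``eta2_c`` are stored against the rescaled growing basis
    ``exp(-k_i*(L-x))`` (i.e. they equal the textbook amplitudes times
    ``exp(k_i*L)``), which keeps every quantity bounded for large ``|s|``.
    """

    k1: np.ndarray
    k2: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    eta1_c: np.ndarray
    eta2_c: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray


def transform_coefficients(s, p: DimensionlessParams) -> TransformCoefficients:
    """Evaluate ``a1``, ``a2``, ``Q~`` and the quartic invariants ``ell``, ``m``."""
    s = np.atleast_1d(np.asarray(s, dtype=complex))
    denom = 1.0 + p.tau_T * s
    if np.any(s == 0) or np.any(denom == 0):
        raise SingularCoefficientError(
            "coefficients are singular at s = 0 or 1 + tau_T*s = 0")
    lag_ratio = (1.0 + p.tau_q * s) / denom
    a1 = lag_ratio * (s + p.beta1)
    a2 = lag_ratio * p.beta2
    q_tilde = p.Q / (s * denom)
    ell = a1 + s ** 2 + a2 * p.beta3
    m = a1 * s ** 2
    return TransformCoefficients(s=s, a1=a1, a2=a2, Q_tilde=q_tilde, ell=ell, m=m)


def _principal_nonneg(k: np.ndarray) -> np.ndarray:
    """Square roots mapped onto the Re >= 0 half-plane (Im >= 0 on the boundary)."""
    flip = (k.real < 0) | ((k.real == 0) & (k.imag < 0))
    return np.where(flip, -k, k)


def characteristic_roots(tc: TransformCoefficients) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``k**4 - ell*k**2 + m = 0`` for the two decay exponents.

    Returns ``(k1, k2)`` with non-negative real parts, ordered by modulus
    (ties broken by smaller imaginary part).
    """
    ell, m = tc.ell, tc.m
    if np.any((ell == 0) & (m == 0)):
        raise DegenerateRootsError("characteristic quartic degenerates: ell = m = 0")
    disc = np.sqrt(ell ** 2 - 4.0 * m)
    # stable quadratic roots: form the larger root without cancellation, then
    # recover the smaller one from the product (Vieta); on the inversion
    # contour ell and disc nearly coincide, so (ell - disc)/2 loses all digits
    disc = np.where((ell.conjugate() * disc).real >= 0, disc, -disc)
    z_b = 0.5 * (ell + disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_a = np.where(z_b != 0, m / np.where(z_b != 0, z_b, 1.0),
                       0.5 * (ell - disc))
    k_a = _principal_nonneg(np.sqrt(z_a))
    k_b = _principal_nonneg(np.sqrt(z_b))
    swap = (np.abs(k_a) > np.abs(k_b)) | (
        (np.abs(k_a) == np.abs(k_b)) & (k_a.imag > k_b.imag))
    k1 = np.where(swap, k_b, k_a)
    k2 = np.where(swap, k_a, k_b)
    return k1, k2


def strain_mode_weights(tc: TransformCoefficients,
                        roots: tuple[np.ndarray, np.ndarray],
                        p: DimensionlessParams) -> tuple[np.ndarray, np.ndarray]:
    """Cancellation-free evaluation of ``d_i = k_i**2 - a1``.

    At the quartic roots ``(z - a1)*(z - s**2) = a2*beta3*z`` holds exactly, so
    whichever of the two differences is the small one can be recovered from the
    large one without subtractive cancellation.  For the root shadowing ``a1``
    (thermal mode) the identity form is used; for the root shadowing ``s**2``
    (elastic mode) the direct difference is already stable.
    """
    out = []
    for k in roots:
        z = k ** 2
        direct = z - tc.a1
        elastic_gap = z - tc.s ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            via_identity = tc.a2 * p.beta3 * z / np.where(elastic_gap != 0,
                                                          elastic_gap, 1.0)
        use_identity = (np.abs(direct) <= np.abs(elastic_gap)) & (elastic_gap != 0)
        out.append(np.where(use_identity, via_identity, direct))
    return out[0], out[1]


def boundary_amplitudes(tc: TransformCoefficients,
                        roots: tuple[np.ndarray, np.ndarray],
                        g_bar,
                        p: DimensionlessParams) -> ModeCoefficients:
    """Solve the 4x4 boundary system for the mode amplitudes.

    Rows are the two thermal boundary conditions and the two (strain-form)
    traction-free conditions; unknowns are ``[eps1, eps2, eta1_c, eta2_c]``
    in the rescaled basis described in :class:`ModeCoefficients`.  The data
    are ``alpha1 = g_bar - Q~/a1`` and ``alpha2 = beta3*g_bar``.
    """
    k1, k2 = roots
    s = tc.s
    g_bar = np.broadcast_to(np.asarray(g_bar, dtype=complex), s.shape)
    alpha1 = g_bar - tc.Q_tilde / tc.a1
    alpha2 = p.beta3 * g_bar

    e1 = np.exp(-k1 * p.L)
    e2 = np.exp(-k2 * p.L)
    d1, d2 = strain_mode_weights(tc, (k1, k2), p)

    n = s.size
    mat = np.empty(s.shape + (4, 4), dtype=complex)
    one = np.ones_like(s)
    # theta_bar(0) = g_bar
    mat[..., 0, 0] = one; mat[..., 0, 1] = one
    mat[..., 0, 2] = e1;  mat[..., 0, 3] = e2
    # theta_bar(L) = 0
    mat[..., 1, 0] = e1;  mat[..., 1, 1] = e2
    mat[..., 1, 2] = one; mat[..., 1, 3] = one
    # e_bar(0) = beta3*g_bar  (scaled by a2)
    mat[..., 2, 0] = d1;       mat[..., 2, 1] = d2
    mat[..., 2, 2] = d1 * e1;  mat[..., 2, 3] = d2 * e2
    # e_bar(L) = 0
    mat[..., 3, 0] = d1 * e1;  mat[..., 3, 1] = d2 * e2
    mat[..., 3, 2] = d1;       mat[..., 3, 3] = d2

    rhs = np.empty(s.shape + (4,), dtype=complex)
    rhs[..., 0] = alpha1
    rhs[..., 1] = -tc.Q_tilde / tc.a1
    rhs[..., 2] = tc.a2 * alpha2
    rhs[..., 3] = 0.0

    # Row equilibration: the strain rows carry the factors d_i which grow like
    # s**2 on the contour; rescaling them keeps the pivoting well behaved.
    scale = np.maximum(np.maximum(np.abs(d1), np.abs(d2)), 1.0)
    mat[..., 2, :] /= scale[..., None]
    mat[..., 3, :] /= scale[..., None]
    rhs[..., 2] /= scale
    rhs[..., 3] /= scale

    try:
        sol = np.linalg.solve(mat, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"boundary-amplitude system is singular: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError("boundary-amplitude solve produced non-finite values")

    resid = np.abs(np.einsum("...ij,...j->...i", mat, sol) - rhs)
    ref = np.maximum(np.abs(rhs), 1.0)
    worst = float(np.max(resid / ref)) if n else 0.0
    if worst > _RESIDUAL_TOL:
        raise SingularSystemError(
            f"boundary-amplitude solve residual {worst:.3e} exceeds tolerance "
            f"{_RESIDUAL_TOL:.1e} (ill-conditioned system)",
            condition_estimate=worst / np.finfo(float).eps)

    return ModeCoefficients(k1=k1, k2=k2,
                            eps1=sol[..., 0], eps2=sol[..., 1],
                            eta1_c=sol[..., 2], eta2_c=sol[..., 3],
                            alpha1=alpha1, alpha2=alpha2)


def _mode_sums(x, mc: ModeCoefficients, tc: TransformCoefficients, p):
    """Per-mode exponential sums and their x-derivatives at positions ``x``.

    Returns ``(sum0, sum1, dsum0, dsum1)`` where ``sum_i`` is
    ``eps_i*exp(-k_i*x) + eta_i_c*exp(-k_i*(L-x))`` with shapes ``s.shape + x.shape``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > p.L):
        raise DomainError(f"x must lie in [0, {p.L}]")
    sl = (...,) + (None,) * x.ndim
    modes = []
    for k, eps, eta in ((mc.k1, mc.eps1, mc.eta1_c), (mc.k2, mc.eps2, mc.eta2_c)):
        down = np.exp(-k[sl] * x)
        up = np.exp(-k[sl] * (p.L - x))
        val = eps[sl] * down + eta[sl] * up
        der = k[sl] * (-eps[sl] * down + eta[sl] * up)
        modes.append((val, der, k))
    return modes


def field_transforms(x, mc: ModeCoefficients, tc: TransformCoefficients,
                     p: DimensionlessParams):
    """Evaluate ``(theta_bar, e_bar, sigma_bar, u_bar)`` at positions ``x``.

    The displacement transform is recovered constant-free from the
    Laplace-domain motion balance, ``u_bar = (1/s**2) * d(sigma_bar)/dx``,
    with the derivative taken analytically on the exponential modes.
    Output shapes are ``s.shape + x.shape``.
    """
    if p.beta2 == 0:
        raise SingularSystemError(
            "beta2 = 0 decouples the system; use solve_field_transforms")
    modes = _mode_sums(x, mc, tc, p)
    sl = (...,) + (None,) * np.ndim(x)
    s2 = (tc.s ** 2)[sl]
    a2 = tc.a2[sl]
    theta = tc.Q_tilde[sl] / tc.a1[sl]
    e_bar = 0.0
    de_bar = 0.0
    dtheta = 0.0
    weights = strain_mode_weights(tc, (mc.k1, mc.k2), p)
    for (val, der, k), d_full in zip(modes, weights):
        d_i = d_full[sl]
        theta = theta + val
        dtheta = dtheta + der
        e_bar = e_bar + d_i * val / a2
        de_bar = de_bar + d_i * der / a2
    sigma = e_bar - p.beta3 * theta
    u_bar = (de_bar - p.beta3 * dtheta) / s2
    return theta, e_bar, sigma, u_bar


def _solve_two_point(kappa, length, left, right):
    """Amplitudes (A, B) of ``A*exp(-kappa*x) + B*exp(-kappa*(length-x))``
    matching prescribed values at x=0 and x=length (vectorised)."""
    e = np.exp(-kappa * length)
    det = 1.0 - e ** 2
    if np.any(det == 0):
        raise SingularSystemError("two-point exponential system is singular")
    a = (left - right * e) / det
    b = (right - left * e) / det
    return a, b


def _decoupled_field_transforms(x, tc, g_bar, p):
    """beta2 = 0 limit: conduction decouples; strain is driven by theta.

    theta solves its own two-point problem with modes exp(-+k1*x),
    k1 = sqrt(a1); the strain equation then has theta as a source, a
    particular solution proportional to the thermal modes, and elastic
    homogeneous modes exp(-+s*x) fixed by e(0)=beta3*g_bar, e(L)=0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > p.L):
        raise DomainError(f"x must lie in [0, {p.L}]")
    s = tc.s
    k1 = _principal_nonneg(np.sqrt(tc.a1))
    k2 = _principal_nonneg(np.sqrt(s.astype(complex) ** 2))
    if np.any(np.abs(tc.a1 - s ** 2) == 0):
        raise DegenerateRootsError("thermal and elastic modes coincide (a1 = s**2)")
    g_bar = np.broadcast_to(np.asarray(g_bar, dtype=complex), s.shape)
    part = tc.Q_tilde / tc.a1
    th_a, th_b = _solve_two_point(k1, p.L, g_bar - part, -part)

    # particular strain response to the thermal modes
    c_p = p.beta3 * tc.a1 / (tc.a1 - s ** 2)
    e0_target = p.beta3 * g_bar
    ep_a, ep_b = c_p * th_a, c_p * th_b
    e_left = e0_target - (ep_a + ep_b * np.exp(-k1 * p.L))
    e_right = -(ep_a * np.exp(-k1 * p.L) + ep_b)
    eh_a, eh_b = _solve_two_point(k2, p.L, e_left, e_right)

    sl = (...,) + (None,) * x.ndim
    down1 = np.exp(-k1[sl] * x); up1 = np.exp(-k1[sl] * (p.L - x))
    down2 = np.exp(-k2[sl] * x); up2 = np.exp(-k2[sl] * (p.L - x))
    theta = th_a[sl] * down1 + th_b[sl] * up1 + part[sl]
    dtheta = k1[sl] * (-th_a[sl] * down1 + th_b[sl] * up1)
    e_bar = ep_a[sl] * down1 + ep_b[sl] * up1 + eh_a[sl] * down2 + eh_b[sl] * up2
    de_bar = (k1[sl] * (-ep_a[sl] * down1 + ep_b[sl] * up1)
              + k2[sl] * (-eh_a[sl] * down2 + eh_b[sl] * up2))
    sigma = e_bar - p.beta3 * theta
    u_bar = (de_bar - p.beta3 * dtheta) / (s ** 2)[sl]
    return theta, e_bar, sigma, u_bar


def solve_field_transforms(s, p: DimensionlessParams, g_bar, x):
    """End-to-end Laplace-domain solve: ``(theta_bar, e_bar, sigma_bar, u_bar)``.

    ``s`` may be a scalar or an array of contour points; ``g_bar`` the loading
    transform at those points; ``x`` scalar or grid.  Dispatches to the
    decoupled branch when ``beta2 = 0``.
    """
    scalar_s = np.ndim(s) == 0
    s_arr = np.atleast_1d(np.asarray(s, dtype=complex))
    g_arr = np.broadcast_to(np.asarray(g_bar, dtype=complex), s_arr.shape)
    tc = transform_coefficients(s_arr, p)
    if p.beta2 == 0:
        out = _decoupled_field_transforms(x, tc, g_arr, p)
    else:
        roots = characteristic_roots(tc)
        mc = boundary_amplitudes(tc, roots, g_arr, p)
        out = field_transforms(x, mc, tc, p)
    if scalar_s:
        out = tuple(np.squeeze(f, axis=0) for f in out)
    return out
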