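"""Finite-difference time-domain solver of the coupled dimensionless system.

An independent brute-force route used to validate the Laplace-domain pipeline
on small instances.  The dimensionless equations

    (1 + tau_T d/dt) theta_xx = (1 + tau_q d/dt) theta_t
                                + beta1 (1 + tau_q d/dt) theta
                                + beta2 (1 + tau_q d/dt) e - Q
    e_tt = e_xx - beta3 theta_xx
    sigma = e - beta3 theta

are marched from zero initial data with boundary conditions
``theta(0,t) = g(t)``, ``theta(L,t) = 0`` and traction-free faces
(``e(0,t) = beta3 g(t)``, ``e(L,t) = 0``).

Scheme: the conduction equation is discretised implicitly in time (BDF2-type
differences for d/dt and d2/dt2, the mixed term ``tau_T d/dt theta_xx`` as the
BDF2 difference of the second-difference stencil), yielding one constant
tridiagonal solve per step; the hyperbolic motion equation is advanced by
explicit leapfrog under the CFL restriction ``dt <= dx`` (dimensionless wave
speed one).  Each step first advances the strain with the current temperature,
then the temperature with the fresh strain — no lagging of the coupling terms.
This is a correctness instrument, not a production PDE solver.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .core_params import DimensionlessParams
from .errors import NumericalInstabilityError, StabilityError
from .loading import LoadingSpec

__all__ = ["FDGrid", "make_grid", "fd_solve", "fd_stress"]

_BLOWUP = 1e8


@dataclass
class FDGrid:
    """Space-time grid and (after :func:`fd_solve`) the computed fields.

    ``theta_field`` and ``strain_field`` have shape ``(nt + 1, nx)`` with row
    ``n`` holding time ``n*dt``.
    """

    nx: int
    dt: float
    t_end: float
    x: np.ndarray | None = None
    times: np.ndarray | None = None
    theta_field: np.ndarray | None = None
    strain_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nx < 11:
            raise StabilityError(f"nx must be >= 11, got {self.nx}")
        if not self.dt > 0 or not self.t_end > 0:
            raise StabilityError("dt and t_end must be > 0")

    def sample(self, field: np.ndarray, x_pts, t: float) -> np.ndarray:
        """Values of a stored field at positions ``x_pts`` and time ``t`` (on-grid)."""
        row = int(round(t / self.dt))
        if not np.isclose(row * self.dt, t, rtol=0, atol=1e-12 + 1e-9 * self.dt):
            raise StabilityError(f"t={t} is not a multiple of dt={self.dt}")
        return np.interp(np.asarray(x_pts, dtype=float), self.x, field[row])


def make_grid(p: DimensionlessParams, nx: int, t_end: float,
              cfl: float = 0.5) -> FDGrid:
    """Build a grid whose time step satisfies the CFL bound and divides ``t_end``."""
    dx = p.L / (nx - 1)
    if not 0 < cfl <= 1:
        raise StabilityError(f"cfl must be in (0, 1], got {cfl}")
    nt = max(1, int(np.ceil(t_end / (cfl * dx))))
    return FDGrid(nx=nx, dt=t_end / nt, t_end=t_end)


def fd_solve(p: DimensionlessParams, load: LoadingSpec, grid: FDGrid) -> FDGrid:
    """Time-march the coupled system and fill ``grid`` with theta and strain."""
    nx, dt = grid.nx, grid.dt
    dx = p.L / (nx - 1)
    if dt > dx * (1.0 + 1e-12):
        raise StabilityError(f"CFL violated: dt={dt} > dx={dx}")
    nt = int(round(grid.t_end / dt))
    if not np.isclose(nt * dt, grid.t_end, rtol=1e-9, atol=0):
        raise StabilityError("dt must divide t_end (use make_grid)")

    x = np.linspace(0.0, p.L, nx)
    times = dt * np.arange(nt + 1)
    g = load.time_value(times)

    # Row 0 is the zero initial state everywhere, boundary included: a loading
    # that is already "on" at t=0 (shock with nu=0) is then seen by the march
    # as a one-step transition, which converges to the impulsive initial layer
    # the mixed tau_T*d/dt(theta_xx) term generates from the boundary jump.
    theta = np.zeros((nt + 1, nx))
    strain = np.zeros((nt + 1, nx))

    inv_dx2 = 1.0 / dx ** 2

    def d2(v):
        return (v[:-2] - 2.0 * v[1:-1] + v[2:]) * inv_dx2

    # constant implicit operator: c1 * D2 - c2 * I on the interior unknowns
    c1 = 1.0 + 3.0 * p.tau_T / (2.0 * dt)
    c2 = (3.0 / (2.0 * dt) + p.tau_q / dt ** 2
          + p.beta1 * (1.0 + 3.0 * p.tau_q / (2.0 * dt)))
    n_int = nx - 2
    ab = np.zeros((3, n_int))
    ab[0, 1:] = c1 * inv_dx2
    ab[1, :] = -2.0 * c1 * inv_dx2 - c2
    ab[2, :-1] = c1 * inv_dx2

    th_prev = theta[0].copy()      # fictitious t=-dt history: zero data,
    e_prev = strain[0].copy()      # zero velocity
    th_now = theta[0].copy()
    e_now = strain[0].copy()

    for step in range(1, nt + 1):
        g_new = g[step]
        # --- leapfrog strain update (explicit, uses theta at the old level)
        e_new = np.empty(nx)
        e_new[1:-1] = (2.0 * e_now[1:-1] - e_prev[1:-1]
                       + dt ** 2 * (d2(e_now) - p.beta3 * d2(th_now)))
        e_new[0] = p.beta3 * g_new
        e_new[-1] = 0.0

        # --- implicit conduction update with the fresh strain
        known = (p.tau_T * (-4.0 * d2(th_now) + d2(th_prev)) / (2.0 * dt)
                 + (4.0 * th_now[1:-1] - th_prev[1:-1]) / (2.0 * dt)
                 + p.tau_q * (2.0 * th_now[1:-1] - th_prev[1:-1]) / dt ** 2
                 + p.beta1 * p.tau_q * (4.0 * th_now[1:-1] - th_prev[1:-1]) / (2.0 * dt)
                 - p.beta2 * (e_new[1:-1] + p.tau_q * (3.0 * e_new[1:-1]
                              - 4.0 * e_now[1:-1] + e_prev[1:-1]) / (2.0 * dt))
                 + p.Q)
        rhs = -known
        # Dirichlet contributions of the new boundary values to c1*D2
        rhs[0] -= c1 * inv_dx2 * g_new
        # theta(L) = 0 contributes nothing
        th_new = np.empty(nx)
        th_new[1:-1] = solve_banded((1, 1), ab, rhs)
        th_new[0] = g_new
        th_new[-1] = 0.0

        if not np.all(np.isfinite(th_new)) or np.max(np.abs(th_new)) > _BLOWUP \
                or np.max(np.abs(e_new)) > _BLOWUP:
            raise NumericalInstabilityError(
                f"finite-difference march blew up at step {step} (t={step * dt:g})")

        theta[step] = th_new
        strain[step] = e_new
        th_prev, th_now = th_now, th_new
        e_prev, e_now = e_now, e_new

    grid.x = x
    grid.times = times
    grid.theta_field = theta
    grid.strain_field = strain
    return grid


def fd_stress(p: DimensionlessParams, grid: FDGrid) -> np.ndarray:
    """Recover the stress field ``sigma = e - beta3*theta`` from a solved grid."""
    if grid.theta_field is None:
        raise StabilityError("grid has not been solved yet")
    return grid.strain_field - p.beta3 * grid.theta_field
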