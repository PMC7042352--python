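"""The three surface thermal loading programs and their Laplace transforms.

The heated boundary ``x = 0`` is driven by a prescribed temperature increment
``theta(0, t) = g(t)`` with one of three shapes:

* ``thermal_shock`` — a delayed Heaviside step ``theta0 * H(t - nu)``;
* ``ramp`` — a linear rise to ``theta0`` over the ramping time ``t0``;
* ``harmonic`` — an oscillatory program of angular parameter ``omega``.

The harmonic case carries a dialect switch.  The conventional closed-form
transform for the harmonic program, ``theta0*omega/(s**2 - omega**2)``, is the
transform of ``theta0*sinh(omega*t)`` rather than of ``theta0*sin(omega*t)``,
and the reference boundary values are consistent with the sinh pair.
``harmonic_dialect="as_printed"`` (default) uses that hyperbolic pair to
reproduce the reference curves; ``"standard_sine"`` uses the genuinely
periodic ``sin`` pair ``theta0*omega/(s**2 + omega**2)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError, SingularTransformError

__all__ = ["LoadingSpec", "loading_time_value", "loading_transform",
           "KINDS", "HARMONIC_DIALECTS"]

KINDS = ("thermal_shock", "ramp", "harmonic")
HARMONIC_DIALECTS = ("as_printed", "standard_sine")

_KIND_ALIASES = {"shock": "thermal_shock", "thermal_shock": "thermal_shock",
                 "ramp": "ramp", "harmonic": "harmonic"}


@dataclass(frozen=True)
class LoadingSpec:
    """One surface heating program.

    Only the shape parameter matching ``kind`` is required: ``nu`` (shock delay,
    >= 0), ``t0`` (ramping time, > 0) or ``omega`` (angular parameter, > 0).
    All quantities are dimensionless.
    """

    kind: str
    theta0: float = 1.0
    nu: float | None = None
    t0: float | None = None
    omega: float | None = None
    harmonic_dialect: str = "as_printed"

    def __post_init__(self) -> None:
        kind = _KIND_ALIASES.get(self.kind)
        if kind is None:
            raise InvalidParameterError(
                f"unknown loading kind {self.kind!r}; expected one of {KINDS}")
        object.__setattr__(self, "kind", kind)
        if not self.theta0 > 0:
            raise InvalidParameterError(f"theta0 must be > 0, got {self.theta0}")
        if kind == "thermal_shock":
            nu = 0.0 if self.nu is None else self.nu
            if nu < 0:
                raise InvalidParameterError(f"nu must be >= 0, got {nu}")
            object.__setattr__(self, "nu", nu)
        elif kind == "ramp":
            if self.t0 is None or not self.t0 > 0:
                raise InvalidParameterError(f"ramp requires t0 > 0, got {self.t0}")
        else:
            if self.omega is None or not self.omega > 0:
                raise InvalidParameterError(
                    f"harmonic requires omega > 0, got {self.omega}")
            if self.harmonic_dialect not in HARMONIC_DIALECTS:
                raise InvalidParameterError(
                    f"harmonic_dialect must be one of {HARMONIC_DIALECTS}, "
                    f"got {self.harmonic_dialect!r}")

    # -- time domain ------------------------------------------------------
    def time_value(self, t):
        """Evaluate ``g(t)`` at dimensionless time ``t`` (scalar or array)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise DomainError("loading is defined for t >= 0 only")
        if self.kind == "thermal_shock":
            # H(t - nu) with H(0) = 1: the step is on for t >= nu.
            out = self.theta0 * (t_arr >= self.nu).astype(float)
        elif self.kind == "ramp":
            out = self.theta0 * np.minimum(t_arr / self.t0, 1.0)
        elif self.harmonic_dialect == "standard_sine":
            out = self.theta0 * np.sin(self.omega * t_arr)
        else:
            out = self.theta0 * np.sinh(self.omega * t_arr)
        return out if np.ndim(t) else float(out)

    # -- Laplace domain ---------------------------------------------------
    def transform(self, s):
        """Evaluate the Laplace transform ``g_bar(s)`` (scalar or array, complex)."""
        s_arr = np.asarray(s, dtype=complex)
        if np.any(s_arr == 0):
            raise SingularTransformError("g_bar(s) has a pole at s = 0")
        if self.kind == "thermal_shock":
            out = self.theta0 * np.exp(-self.nu * s_arr) / s_arr
        elif self.kind == "ramp":
            out = self.theta0 * (1.0 - np.exp(-self.t0 * s_arr)) / (self.t0 * s_arr ** 2)
        elif self.harmonic_dialect == "standard_sine":
            denom = s_arr ** 2 + self.omega ** 2
            if np.any(denom == 0):
                raise SingularTransformError("g_bar(s) pole: s**2 = -omega**2")
            out = self.theta0 * self.omega / denom
        else:
            denom = s_arr ** 2 - self.omega ** 2
            if np.any(denom == 0):
                raise SingularTransformError("g_bar(s) pole: s**2 = omega**2")
            out = self.theta0 * self.omega / denom
        return out if np.ndim(s) else complex(out)


def loading_time_value(load: LoadingSpec, t):
    """Functional wrapper around :meth:`LoadingSpec.time_value`."""
    return load.time_value(t)


def loading_transform(load: LoadingSpec, s):
    """Functional wrapper around :meth:`LoadingSpec.transform`."""
    return load.transform(s)
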