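"""Tissue properties and the dimensionless parameter set of the thermoelastic model.

The simulator works entirely in dimensionless variables.  Lengths are scaled by
``1/(c0*eta)`` and times by ``1/(c0**2*eta)``, where ``c0 = sqrt((lambda+2*mu)/rho)``
is the longitudinal elastic wave speed and ``eta = rho*C/K`` the thermal
viscosity.  Temperature increments ``theta = T - T_b`` are scaled by the
reference absolute temperature ``T_0`` and stress by the longitudinal modulus
``lambda + 2*mu``.  Four dimensionless groups govern the coupled system:

``beta1``
    blood-perfusion heat-sink coupling, ``W_b*C_b*rho_b / (c0**2*eta**2*K)``;
``beta2``
    strain-to-heat coupling in the energy equation, ``gamma / (c0**2*eta**2*K)``;
``beta3``
    temperature-to-stress coupling, ``gamma*T_0 / (lambda + 2*mu)``;
``Q``
    metabolic heat source, ``Q_met / (c0**2*eta**2*K)``;

together with the two phase lags ``tau_q`` (heat flux) and ``tau_T``
(temperature gradient) of the dual-phase-lag conduction law and the
dimensionless tissue thickness ``L``.

The default mechanical constants (``lambda_l``, ``mu_l``, ``gamma_c``, ``T_0``)
are a documented calibration: they correspond to a soft tissue with
longitudinal modulus 1 MPa and linear thermal-expansion-type coupling chosen so
that ``beta3 = 0.00773``, the value implied by the traction-free boundary
identity ``e(0,t) = beta3*g(t)`` under unit thermal-shock loading.  See
``docs/methods.md`` for the calibration rationale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

__all__ = [
    "TissueProperties",
    "DimensionlessParams",
    "derive_scales",
    "compute_dimensionless",
    "to_dimensionless_length",
    "to_dimensional_length",
    "to_dimensionless_time",
    "to_dimensional_time",
]

# Calibrated default mechanical set (see module docstring / docs/methods.md).
_BETA3_CAL = 0.00773
_T0_DEFAULT = 310.15          # K, blood temperature 37 degC on the absolute scale
_LAMBDA_DEFAULT = 7.0e5       # Pa
_MU_DEFAULT = 1.5e5           # Pa
_GAMMA_DEFAULT = _BETA3_CAL * (_LAMBDA_DEFAULT + 2.0 * _MU_DEFAULT) / _T0_DEFAULT

# Default dimensionless study conditions used throughout the solver.
_BETA1_DEFAULT = 1.0
_BETA2_DEFAULT = 0.00773
# Q/beta1 is fixed to the physical ratio Q_met/(W_b*C_b*rho_b), which is
# independent of the unknown mechanical scale factor c0**2*eta**2*K.
_Q_DEFAULT = 368.1 / (0.00187 * 3860.0 * 1060.0) * _BETA1_DEFAULT


@dataclass(frozen=True)
class TissueProperties:
    """Dimensional thermal and mechanical constants of skin tissue and blood.

    Thermal defaults are the standard skin-tissue property set; mechanical
    defaults are the calibrated soft-tissue set described in the module
    docstring.  Units are SI with temperatures in degC except ``T_0`` (K).
    """

    K: float = 0.628          # thermal conductivity, W/(m degC)
    rho: float = 1000.0       # tissue density, kg/m^3
    C: float = 4187.0         # tissue specific heat, J/(kg degC)
    rho_b: float = 1060.0     # blood density, kg/m^3
    C_b: float = 3860.0       # blood specific heat, J/(kg degC)
    W_b: float = 0.00187      # blood perfusion rate, 1/s
    T_b: float = 37.0         # arterial (blood) temperature, degC
    Q_met: float = 368.1      # metabolic heat generation, W/m^3
    Q_ext: float = 0.0        # external volumetric heat source, W/m^3 (model assumes 0)
    lambda_l: float = _LAMBDA_DEFAULT   # first Lame-type modulus, Pa
    mu_l: float = _MU_DEFAULT           # second Lame-type modulus, Pa
    gamma_c: float = _GAMMA_DEFAULT     # thermal coupling modulus, Pa/degC
    T_0: float = _T0_DEFAULT            # reference absolute temperature, K

    def __post_init__(self) -> None:
        positive = {"K": self.K, "rho": self.rho, "C": self.C,
                    "C_b": self.C_b, "rho_b": self.rho_b, "T_0": self.T_0}
        for name, value in positive.items():
            if not value > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value}")
        nonneg = {"W_b": self.W_b, "Q_met": self.Q_met}
        for name, value in nonneg.items():
            if value < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value}")
        if not self.lambda_l + 2.0 * self.mu_l > 0:
            raise InvalidParameterError(
                f"longitudinal modulus lambda_l + 2*mu_l must be > 0, "
                f"got {self.lambda_l + 2.0 * self.mu_l}")
        if self.Q_ext != 0.0:
            raise InvalidParameterError(
                "the model assumes no external volumetric heat source (Q_ext = 0)")


@dataclass(frozen=True)
class DimensionlessParams:
    """The dimensionless parameter set the Laplace-domain solver consumes.

    Defaults are the calibrated study conditions: ``beta3 = 0.00773`` fixed by
    the boundary strain identity, symmetric thermomechanical coupling
    ``beta2 = beta3``, unit perfusion coupling, and ``Q`` preserving the
    physical ratio of metabolic heating to perfusion cooling.  ``c0`` and
    ``eta`` are carried only for optional unit conversion and do not enter the
    dimensionless solve.
    """

    beta1: float = _BETA1_DEFAULT
    beta2: float = _BETA2_DEFAULT
    beta3: float = _BETA3_CAL
    Q: float = _Q_DEFAULT
    tau_q: float = 0.02
    tau_T: float = 0.04
    L: float = 0.3
    c0: float | None = field(default=None, compare=False)
    eta: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "beta3", "Q", "tau_q", "tau_T"):
            value = getattr(self, name)
            if value < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value}")
        if not self.L > 0:
            raise InvalidParameterError(f"L must be > 0, got {self.L}")


def derive_scales(props: TissueProperties) -> tuple[float, float]:
    """Longitudinal wave speed ``c0`` [m/s] and thermal viscosity ``eta`` [s/m^2].

    ``c0 = sqrt((lambda_l + 2*mu_l)/rho)`` and ``eta = rho*C/K``.
    """
    modulus = props.lambda_l + 2.0 * props.mu_l
    if modulus <= 0 or props.rho <= 0:
        raise InvalidParameterError("need lambda_l + 2*mu_l > 0 and rho > 0")
    c0 = math.sqrt(modulus / props.rho)
    eta = props.rho * props.C / props.K
    return c0, eta


def compute_dimensionless(props: TissueProperties,
                          tau_q: float = 0.02,
                          tau_T: float = 0.04,
                          L: float = 0.3) -> DimensionlessParams:
    """Derive the dimensionless parameter set from dimensional tissue properties.

    ``tau_q``, ``tau_T`` and ``L`` are already-dimensionless configuration
    values and are copied through unchanged.
    """
    c0, eta = derive_scales(props)
    scale = c0 ** 2 * eta ** 2 * props.K
    beta1 = props.W_b * props.C_b * props.rho_b / scale
    beta2 = props.gamma_c / scale
    beta3 = props.gamma_c * props.T_0 / (props.lambda_l + 2.0 * props.mu_l)
    q_dimless = props.Q_met / scale
    for name, value in (("beta1", beta1), ("beta2", beta2),
                        ("beta3", beta3), ("Q", q_dimless)):
        if value < 0:
            raise InvalidParameterError(f"derived {name} is negative: {value}")
    return DimensionlessParams(beta1=beta1, beta2=beta2, beta3=beta3,
                               Q=q_dimless, tau_q=tau_q, tau_T=tau_T, L=L,
                               c0=c0, eta=eta)


def to_dimensionless_length(x: float, c0: float, eta: float) -> float:
    """Map a dimensional length [m] to its dimensionless image ``x' = c0*eta*x``."""
    return c0 * eta * x


def to_dimensional_length(x_prime: float, c0: float, eta: float) -> float:
    """Invert :func:`to_dimensionless_length`."""
    return x_prime / (c0 * eta)


def to_dimensionless_time(t: float, c0: float, eta: float) -> float:
    """Map a dimensional time [s] to its dimensionless image ``t' = c0**2*eta*t``."""
    return c0 ** 2 * eta * t


def to_dimensional_time(t_prime: float, c0: float, eta: float) -> float:
    """Invert :func:`to_dimensionless_time`."""
    return t_prime / (c0 ** 2 * eta)
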