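"""Exception hierarchy shared across the package."""


class DPLSkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DPLSkinError, ValueError):
    """A tissue property or dimensionless parameter violates its invariant."""


class DomainError(DPLSkinError, ValueError):
    """An evaluation point lies outside the admissible domain (t<0, x outside [0,L], ...)."""


class SingularTransformError(DPLSkinError, ZeroDivisionError):
    """A Laplace-domain expression was requested at one of its poles."""


class SingularCoefficientError(SingularTransformError):
    """The per-s coefficients a1, a2, Q~ are singular (s=0 or 1+tau_T*s=0)."""


class DegenerateRootsError(DPLSkinError, ArithmeticError):
    """The characteristic quartic degenerates (ell=m=0) or its modes coincide."""


class SingularSystemError(DPLSkinError, ArithmeticError):
    """The 4x4 boundary-amplitude system is singular or numerically unusable."""

    def __init__(self, msg: str, condition_estimate: float | None = None):
        super().__init__(msg)
        self.condition_estimate = condition_estimate


class TransformEvaluationError(DPLSkinError, RuntimeError):
    """The user-supplied transform raised while being evaluated at a contour node."""

    def __init__(self, msg: str, node_index: int | None = None, s_value: complex | None = None):
        super().__init__(msg)
        self.node_index = node_index
        self.s_value = s_value


class StabilityError(DPLSkinError, ValueError):
    """The finite-difference grid violates its stability restriction."""


class NumericalInstabilityError(DPLSkinError, ArithmeticError):
    """A finite-difference march blew up (field magnitude diverged)."""
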