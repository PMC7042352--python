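import dataclasses

import numpy as np
import pytest

from dplskin import DimensionlessParams, InversionOptions


@pytest.fixture
def params() -> DimensionlessParams:
    """Default calibrated dimensionless study conditions."""
    return DimensionlessParams()


@pytest.fixture
def decoupled_params(params) -> DimensionlessParams:
    """Thermomechanically decoupled variant (beta2 = beta3 = 0)."""
    return dataclasses.replace(params, beta2=0.0, beta3=0.0)


@pytest.fixture
def fast_opts() -> InversionOptions:
    """Adaptive inversion options sized for quick unit tests."""
    return InversionOptions(n_terms=2000, rel_tol=1e-5, n_max=1 << 17)


@pytest.fixture
def fixed_opts() -> InversionOptions:
    """Deterministic fixed-N inversion ("reference mode")."""
    return InversionOptions(n_terms=5000, adaptive=False)


@pytest.fixture
def contour_points() -> np.ndarray:
    """A reproducible spread of complex frequencies on a typical inversion contour."""
    rng = np.random.default_rng(20260922)
    kappa = 4.7 / 0.05
    n = rng.integers(1, 5000, size=64)
    return kappa + 1j * np.pi * n / 0.05
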