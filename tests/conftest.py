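"""Shared fixtures: models and providers at two resolutions.

The "fast" fixtures (512-point grid, reduced frequency counts) keep unit
tests quick; the acceptance tests use the full default model.  All
Green's-matrix providers memoize per (frequency, mode), so sharing them
session-wide avoids recomputation across tests.
"""

import warnings

import numpy as np
import pytest

from cochamp import (
    Cochlea2DConfig,
    Cochlea2DModel,
    CochlearGeometry,
    CochlearModel,
    WKBProvider,
    enhancement_profile_broadband,
    enhancement_profile_narrowband,
)
from cochamp.waveguide import GradientWarning


@pytest.fixture(autouse=True)
def _quiet_gradient_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GradientWarning)
        yield


@pytest.fixture(scope="session")
def model_fast() -> CochlearModel:
    return CochlearModel(CochlearGeometry(grid=512))


@pytest.fixture(scope="session")
def model_default() -> CochlearModel:
    return CochlearModel()


@pytest.fixture(scope="session")
def provider_fast(model_fast) -> WKBProvider:
    return WKBProvider(model_fast)


@pytest.fixture(scope="session")
def provider_default(model_default) -> WKBProvider:
    return WKBProvider(model_default)


@pytest.fixture(scope="session")
def model2d_coarse() -> Cochlea2DModel:
    return Cochlea2DModel(Cochlea2DConfig(grid_nx=256, grid_ny=16))


@pytest.fixture(scope="session")
def default_profiles(provider_default):
    """Narrowband and broadband enhancement at the full default settings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GradientWarning)
        nb = enhancement_profile_narrowband(provider_default)
        bb = enhancement_profile_broadband(provider_default, narrowband=nb)
    return nb, bb


class UniformModel(CochlearModel):
    """Spatially uniform medium: constant complex wavenumber.

    Closed-form limit used by WKB/FD oracle tests: the Green's function
    is exp(-i k |x - x'|) / (2 i k).
    """

    def __init__(self, k0: complex, grid: int = 800, length: float = 5e-3):
        super().__init__(CochlearGeometry(length=length, grid=grid))
        self.k0 = complex(k0)

    def wavenumber(self, x, omega, active, ablate_cutoff=False):
        return np.full(np.asarray(x, dtype=float).shape, self.k0)


@pytest.fixture(scope="session")
def uniform_model() -> UniformModel:
    return UniformModel(k0=5000.0 - 200.0j)
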