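import warnings

import numpy as np
import pytest

from magnetherm.config import DEFAULTS
from magnetherm.relaxation import ParticleModel


@pytest.fixture
def fig8_particle() -> ParticleModel:
    """Magnetite parameter set used for the relaxation-regime surfaces:
    Ms = 450 kA/m, K = 2e4 J/m^3, 2 nm shell, water, 300 K."""
    return ParticleModel(D=16e-9, Ms_vol=4.5e5, K=2.0e4,
                         shell=DEFAULTS.shell_map, tau0=1e-9, T=300.0,
                         eta=1e-3)


@pytest.fixture
def study_Ms_vol() -> float:
    """Volume magnetization of the x=0.3 sample at room temperature."""
    return 93.4 * DEFAULTS.density


@pytest.fixture(autouse=True)
def _quiet_validity_warnings():
    """Validity-range warnings (xi >= 20, h > 0.4) are expected when tests
    probe asymptotic regimes; keep them out of the report."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
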