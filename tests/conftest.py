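import numpy as np
import pytest

from nanopk.model import DoseRegimen, FixedEffects
from nanopk.population import VariabilitySpec
from nanopk.trial import default_design


@pytest.fixture(scope="session")
def typical() -> FixedEffects:
    """Published typical-subject parameter set."""
    return FixedEffects()


@pytest.fixture(scope="session")
def regimen_50_80() -> DoseRegimen:
    """Highest studied cohort: 50 mg/m^2 SN-38, 80 mg/m^2 irinotecan."""
    return DoseRegimen(dose_iri_per_m2=80.0, dose_sn38_per_m2=50.0)


@pytest.fixture(scope="session")
def variability() -> VariabilitySpec:
    return VariabilitySpec()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
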