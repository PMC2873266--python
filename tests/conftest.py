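import numpy as np
import pytest

from mshaz.battery import battery, battery_by_name
from mshaz.model import two_mutation_model


@pytest.fixture(scope="session")
def tsce_spec():
    """Canonical promotion-dominant two-stage clonal expansion model."""
    return battery_by_name("tsce").spec


@pytest.fixture(scope="session")
def ident_spec():
    """Conversion-dominant two-stage model for identifiability studies."""
    return battery_by_name("tsce-ident").spec


@pytest.fixture(scope="session")
def battery_specs():
    return battery()


@pytest.fixture(scope="session")
def coarse_grid():
    return np.arange(0.0, 110.0 + 1e-9, 2.0)


@pytest.fixture(scope="session")
def unreachable_spec():
    """Two-stage model whose malignant transition rate is zero."""
    return two_mutation_model(1e7, 1e-7, 0.0, 0.1, 0.09)
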