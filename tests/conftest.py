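import numpy as np
import pytest

from stroke_cea import default_lifetable, default_parameter_set
from stroke_cea.lifetable import LifeTable


@pytest.fixture(scope="session")
def params():
    """The shipped default parameter set (published input tables)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def lifetable():
    """The bundled synthetic Gompertz-Makeham female life table."""
    return default_lifetable()


@pytest.fixture(scope="session")
def immortal_lifetable():
    """Zero-mortality table spanning every age the model can reach."""
    ages = np.arange(0, 160)
    return LifeTable(sex_label="female", ages=ages, qx=np.zeros_like(ages, dtype=float))
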