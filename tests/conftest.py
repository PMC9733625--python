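import numpy as np
import pytest

from tremor_cea import base_case
from tremor_cea.parameters import LifeTable


@pytest.fixture(scope="session")
def base():
    """The bundled base-case model inputs (England, 2019 GBP)."""
    return base_case()


@pytest.fixture(scope="session")
def zero_mortality_table():
    """A life table with no deaths, covering ages 40-110."""
    ages = np.arange(40, 111)
    zeros = np.zeros_like(ages, dtype=float)
    return LifeTable(ages, zeros, zeros)


@pytest.fixture()
def immortal(base, zero_mortality_table):
    """Base case with mortality switched off."""
    return base.replace(life_table=zero_mortality_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190)
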