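import math

import numpy as np
import pytest
from hypothesis import settings

from soilc14 import AtmosphericRecord, packaged_atmosphere
from soilc14.radiocarbon import LAMBDA_14C

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bomb_record() -> AtmosphericRecord:
    """The packaged synthetic bomb curve (1900-2030)."""
    return packaged_atmosphere()


@pytest.fixture(scope="session")
def unit_fm_record() -> AtmosphericRecord:
    """Atmosphere with fraction modern exactly 1 in every year 1850-1960.

    Under this forcing the pool equilibria have the closed forms
    F_fast = k_f/(k_f+lambda), F_slow = F_fast * k_s/(k_s+lambda).
    """
    years = np.arange(1850.0, 1961.0)
    deltas = np.array(
        [(math.exp(LAMBDA_14C * (1950 - y)) - 1.0) * 1000.0 for y in years]
    )
    return AtmosphericRecord(years=years, delta14c=deltas)


@pytest.fixture(scope="session")
def dead_record() -> AtmosphericRecord:
    """Radiocarbon-free atmosphere (-1000 permil throughout)."""
    years = np.arange(1900.0, 2031.0)
    return AtmosphericRecord(years=years, delta14c=np.full(years.size, -1000.0))
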