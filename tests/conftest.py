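import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ivpk import (
    MacroParams,
    TYPICAL_MACRO_2C,
    macro_to_micro,
    simulate_subject_profile,
    typical_micro_2c,
)

MEAN_DOSE_NG = 9.113333333333333 * 0.3 * 1e6  # mean study body weight x 0.3 mg/kg


@pytest.fixture(scope="session")
def typical_macro() -> MacroParams:
    return TYPICAL_MACRO_2C


@pytest.fixture(scope="session")
def typical_micro():
    return typical_micro_2c(MEAN_DOSE_NG)


@pytest.fixture(scope="session")
def noiseless_profile(typical_micro):
    return simulate_subject_profile(typical_micro, MEAN_DOSE_NG, subject_id="noiseless")


@pytest.fixture(scope="session")
def micro_3c():
    """A well-separated three-compartment parameter set."""
    macro = MacroParams(coefficients=(500.0, 150.0, 20.0), exponents=(12.0, 0.8, 0.09))
    return macro_to_micro(macro, MEAN_DOSE_NG), macro


def assert_close(a, b, rtol=1e-9, atol=0.0):
    np.testing.assert_allclose(a, b, rtol=rtol, atol=atol)
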