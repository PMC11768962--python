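from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from synfounder import collapse_to_ga3, selfed_line_array

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ga4():
    return selfed_line_array()


@pytest.fixture(scope="session")
def ga3():
    return collapse_to_ga3(selfed_line_array())


@pytest.fixture(scope="session")
def f_grid():
    """Line-inbreeding levels used for exact checks."""
    return [Fraction(0), Fraction(1, 4), Fraction(1, 2), Fraction(3, 4), Fraction(1)]
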