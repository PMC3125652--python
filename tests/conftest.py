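import numpy as np
import pytest

from basalmorph import load_reference_cohort
from basalmorph.morphometry import variable_values


@pytest.fixture(scope="session")
def cohort():
    """The packaged 70-case reference cohort (10 normal / 30 / 30)."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def cohort_values(cohort):
    """Column accessor: cohort_values(group, variable) -> ndarray."""

    def get(group: str, variable: str) -> np.ndarray:
        return variable_values([r for r in cohort if r.group == group], variable)

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
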