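import numpy as np
import pytest

from sanibound import load_fixture
from sanibound.well_data import GuidelineEntry, GuidelineTable


@pytest.fixture(scope="session")
def guidelines():
    return load_fixture("guidelines")


@pytest.fixture(scope="session")
def wells28():
    return load_fixture("validation_wells")


@pytest.fixture(scope="session")
def published_fit():
    return load_fixture("regression")


@pytest.fixture(scope="session")
def published_corr():
    return load_fixture("correlations")


@pytest.fixture(scope="session")
def toy_guidelines():
    """Two-parameter table with weights 0.7/0.3 and standards 10/100."""
    return GuidelineTable(
        (
            GuidelineEntry("A", "mg/l", 10.0, relative_weight=0.7),
            GuidelineEntry("B", "mg/l", 100.0, relative_weight=0.3),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
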