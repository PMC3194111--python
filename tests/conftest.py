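import pytest

from radonrisk import load_coefficients, load_constants
from radonrisk.types import CountyContext, DemographicBin


@pytest.fixture(scope="session")
def radon_params():
    return load_coefficients("radon")


@pytest.fixture(scope="session")
def housing_params():
    return load_coefficients("housing")


@pytest.fixture(scope="session")
def smoking_params():
    return load_coefficients("smoking")


@pytest.fixture(scope="session")
def constants():
    return load_constants()[0]


@pytest.fixture(scope="session")
def unit_risks():
    return load_constants()[1]


@pytest.fixture
def reference_bin():
    """All-reference demographic profile: female, 45-54, white, above poverty."""
    return DemographicBin(county_id="C1", state_id="S1", age_group="45-54",
                          sex="female", race="white", poverty="above",
                          count=100)


@pytest.fixture
def zero_context():
    """Reference context: Midwest, Low potential, zero covariates/residuals."""
    return CountyContext(county_id="C1", state_id="S1", region="Midwest",
                         geo_potential="Low",
                         heating_infiltration_degree_days=0.0,
                         avg_diurnal_swing=0.0)
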