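import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fortisim import (
    DietaryRecord,
    PopulationParams,
    generate_population,
    recovery_fixture_population,
)


@pytest.fixture
def toy_record() -> DietaryRecord:
    return DietaryRecord(
        id="toy", age=40, sex="F", energy=2000.0, baseline_vitd=4.0,
        supplement=0.0, grams={"milk": 200.0, "bread": 100.0},
    )


@pytest.fixture(scope="session")
def small_population():
    return generate_population(PopulationParams(n_individuals=200, seed=3))


@pytest.fixture(scope="session")
def recovery_population():
    return recovery_fixture_population()
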