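import hypothesis
import pytest

from tracerdiff import Compound

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def co2() -> Compound:
    return Compound("CO2", molar_mass=44.01, critical_temperature=304.13,
                    critical_volume=94.07)


@pytest.fixture
def benzene() -> Compound:
    return Compound("benzene", molar_mass=78.11, critical_temperature=562.0,
                    critical_volume=256.0)


@pytest.fixture
def water() -> Compound:
    return Compound("water", molar_mass=18.015, critical_temperature=647.1,
                    critical_volume=55.95)
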