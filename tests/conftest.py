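import pytest

from isodrought import DroughtIndex, ScenarioSpec, generate_met
from isodrought.synthetic import index_trajectory


@pytest.fixture(scope="session")
def scenario() -> ScenarioSpec:
    """Default growing-season scenario with a 30-day drought to depth 0.3."""
    return ScenarioSpec()


@pytest.fixture(scope="session")
def met(scenario):
    return generate_met(scenario)


@pytest.fixture(scope="session")
def drought_index(scenario) -> DroughtIndex:
    """The prescribed daily index trajectory as a normalized DroughtIndex."""
    return DroughtIndex(
        values=index_trajectory(scenario), source="custom", normalized=True
    )
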