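import pytest

from diagsnp import fixtures
from diagsnp.model import DiagnosticPanel
from diagsnp.synth import ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default noiseless synthetic scenario with all planted categories."""
    return simulate_scenario(ScenarioConfig(seed=3))


@pytest.fixture(scope="session")
def fixture_results():
    """Fitted panel over the packaged 27-variant frequency matrices."""
    return DiagnosticPanel(fixtures.combined_dosage()).fit()


@pytest.fixture(scope="session")
def table4():
    return fixtures.load_table4()


@pytest.fixture(scope="session")
def table5():
    return fixtures.load_table5()
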