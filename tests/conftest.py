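import pytest

from alfies.scenarios import run_figure_scenarios


@pytest.fixture(scope="session")
def figure_panels():
    """The 12-panel simulation grid at full 1-MHz / 1-s study conditions."""
    panels, table = run_figure_scenarios(duration=1.0)
    return panels, table
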