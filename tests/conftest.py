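import pytest

from taxoprimer.panel import load_packaged_panel
from taxoprimer.synthetic import MockDbSpec, default_design_targets, generate_mock_db


@pytest.fixture(scope="session")
def mock_db():
    """One seeded mock database with the standard six planted targets."""
    return generate_mock_db(MockDbSpec(seed=11, planted_signatures=default_design_targets()))


@pytest.fixture(scope="session")
def packaged_panel():
    return load_packaged_panel()
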