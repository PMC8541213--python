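import pytest

from lampdiag.synth import canonical_spec, simulate_panel


@pytest.fixture(scope="session")
def canonical():
    """The canonical 7-species panel plus its planted-site truth."""
    return simulate_panel(canonical_spec())


@pytest.fixture(scope="session")
def canonical_panel(canonical):
    return canonical[0]


@pytest.fixture(scope="session")
def canonical_truth(canonical):
    return canonical[1]
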