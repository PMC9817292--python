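import pytest

from smilight.fixtures import fixture_smiles


@pytest.fixture(scope="session")
def all_fixture_smiles() -> list[str]:
    """The package's deterministic collection of >=200 valid SMILES."""
    return fixture_smiles()
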