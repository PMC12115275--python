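import pytest

from sedem import fixtures


@pytest.fixture(scope="session")
def profiles():
    """All bundled reference radius profiles by material name."""
    return fixtures.material_profiles()


@pytest.fixture(scope="session")
def carbamazepine(profiles):
    return profiles["carbamazepine"]
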