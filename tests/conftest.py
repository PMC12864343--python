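import pytest

from pgpear import Condition, SystemParams, get_drug


@pytest.fixture(scope="session")
def system() -> SystemParams:
    return SystemParams()


@pytest.fixture(scope="session")
def reference_condition() -> Condition:
    """The standard panel condition: 1 uM apical dose, 1000 uM P-gp, 6 h."""
    return Condition.from_micromolar(1.0, 1000.0)


@pytest.fixture(scope="session")
def verapamil():
    return get_drug("verapamil")


@pytest.fixture(scope="session")
def amprenavir():
    return get_drug("amprenavir")
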