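import pytest

from zsyntax import parse_aggregate, parse_formula
from zsyntax.fixtures import load_bundle, load_fixture_derivation, load_fixture_kb


@pytest.fixture(scope="session")
def glycolysis_kb():
    return load_fixture_kb("glycolysis")


@pytest.fixture(scope="session")
def glycolysis_derivation():
    return load_fixture_derivation("glycolysis")


@pytest.fixture(scope="session")
def tp53_loop_kb():
    return load_fixture_kb("tp53_loop")


@pytest.fixture(scope="session")
def tp53_loop_derivation():
    return load_fixture_derivation("tp53_loop")


@pytest.fixture(scope="session")
def tp53_degradation_kb():
    return load_fixture_kb("tp53_degradation")


@pytest.fixture(scope="session")
def ffl_kb():
    return load_fixture_kb("ffl")


@pytest.fixture(scope="session")
def ffl_derivation():
    return load_fixture_derivation("ffl")


@pytest.fixture(scope="session")
def phospho_kb():
    return load_fixture_kb("phospho")


@pytest.fixture(scope="session")
def numb_kb():
    return load_fixture_kb("numb")


@pytest.fixture(scope="session")
def glycolysis_ia():
    return parse_aggregate("Glc & HK & GPI & PFK & ATP & ATP")


@pytest.fixture(scope="session")
def numb_ia():
    return parse_aggregate("TP53 & MDM2 & NUMB & U & P")
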