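import pytest

from protoquant.library import default_compound_library
from protoquant.pipeline import quantify_study, simulate_study
from protoquant.synthetic import InstrumentConfig


@pytest.fixture(scope="session")
def library():
    return default_compound_library()


@pytest.fixture(scope="session")
def noiseless_instrument():
    return InstrumentConfig().noiseless()


@pytest.fixture(scope="session")
def noiseless_leaf_study(noiseless_instrument):
    """A leaf population measured without any noise: the round-trip anchor."""
    return simulate_study("leaf-SA", seed=7, instrument=noiseless_instrument)


@pytest.fixture(scope="session")
def noiseless_leaf_quant(noiseless_leaf_study):
    return quantify_study(noiseless_leaf_study)
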