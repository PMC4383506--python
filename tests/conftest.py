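import numpy as np
import pytest

from periclinal import pinot


@pytest.fixture(scope="session")
def panel():
    return pinot.pinot_panel()


@pytest.fixture(scope="session")
def canonical(panel):
    """Canonical colored/white references (SC8_0146_010 unresolved)."""
    return pinot.build_canonical_haplotypes(panel)


@pytest.fixture(scope="session")
def library():
    return pinot.canonical_library()


@pytest.fixture(scope="session")
def sim_library():
    """Library with the arbitrary concrete SC8_0146_010 phase, for simulation."""
    return {h.name: h for h in pinot.canonical_library(concrete_sc8=True)}


@pytest.fixture(scope="session")
def models():
    return pinot.clone_models()


@pytest.fixture(scope="session")
def table1():
    return pinot.table1_genotypes()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
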