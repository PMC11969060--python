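import numpy as np
import pytest

from olims.chem import parse_sequence
from olims.presets import get_preset


@pytest.fixture(scope="session")
def sirna_preset():
    return get_preset("sirna")


@pytest.fixture(scope="session")
def moe_preset():
    return get_preset("moe-aso")


@pytest.fixture(scope="session")
def psdna_preset():
    return get_preset("ps-dna")


@pytest.fixture(scope="session")
def short_rna():
    """Small analyte for fast end-to-end checks (~3.2 kDa)."""
    return parse_sequence("rGrArCrUrGrCrArGrUrC", name="short_rna")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
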