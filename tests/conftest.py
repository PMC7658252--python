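import pytest
from rdkit import RDLogger

from synforge import builtin_rules, prepare
from synforge.engine import run_library
from synforge.fixtures import DEFAULT_SPEC, generate_library

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def standard_rules():
    return builtin_rules()


@pytest.fixture(scope="session")
def toy_library():
    """Default seeded toy building-block library with ground truth."""
    return generate_library(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def prepared_blocks(toy_library):
    return prepare([(r.bb_id, r.smiles) for r in toy_library])


@pytest.fixture(scope="session")
def library_run(standard_rules, prepared_blocks):
    """One full pipeline run over the toy library, shared across tests."""
    return run_library(standard_rules, prepared_blocks)
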