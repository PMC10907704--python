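from pathlib import Path

import pytest

from pvsignal.preprocess import SynonymDictionary, assemble_dataset
from pvsignal.synthetic import generate, toy_config

DATA_DIR = Path(__file__).parent / "data"
FIXTURE_QUARTER = DATA_DIR / "synthetic_toy_quarter"
SYNONYM_FILE = DATA_DIR / "doxorubicin_synonyms.tsv"
GOLDEN_DIR = DATA_DIR / "golden"


@pytest.fixture(scope="session")
def synonym_dict() -> SynonymDictionary:
    return SynonymDictionary.from_file(SYNONYM_FILE)


@pytest.fixture(scope="session")
def toy_bundle_truth():
    """The documented toy quarter (200 cases, 3 groups, 10 PTs, seed 42),
    regenerated in memory; identical to the checked-in fixture files."""
    return generate(toy_config())


@pytest.fixture(scope="session")
def toy_dataset(toy_bundle_truth, synonym_dict):
    bundle, _ = toy_bundle_truth
    return assemble_dataset(bundle, synonym_dict)
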