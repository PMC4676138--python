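import importlib.util
from pathlib import Path

import pytest

from librank.chemio import (
    generate_fixture_library,
    generate_labeled_records,
    records_from_smiles,
)

REPO_ROOT = Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def acceptance_module():
    """The acceptance script, loaded as a module (shares its table inputs)."""
    path = REPO_ROOT / "scripts" / "acceptance.py"
    spec = importlib.util.spec_from_file_location("acceptance_script", path)
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def mixed_fixture():
    """Library with every planted category, plus its ground-truth manifest."""
    return generate_fixture_library(
        {"clean": 8, "salt-form": 2, "inorganic": 2, "mixture": 2, "duplicate-pair": 2, "alert-matching": 3},
        seed=11,
    )


@pytest.fixture(scope="session")
def clustered_labeled():
    """10 well-separated analogue clusters, 8 members each, one label per cluster."""
    records, labels = generate_labeled_records(10, 8, seed=5)
    return records, labels


def make_records(*smiles):
    return records_from_smiles(list(smiles), source="test")


@pytest.fixture
def records_factory():
    return make_records
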