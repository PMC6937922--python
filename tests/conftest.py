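import json
import sys
from pathlib import Path

import pytest
from rdkit import Chem

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from chemvault import chem as cvchem
from chemvault import fixtures, store
from chemvault.api import Server


def molblock(smiles: str) -> str:
    return Chem.MolToMolBlock(Chem.MolFromSmiles(smiles), kekulize=True)


@pytest.fixture(scope="session")
def benzene_molfile() -> str:
    return molblock("c1ccccc1")


@pytest.fixture(scope="session")
def toluene_molfile() -> str:
    return molblock("Cc1ccccc1")


@pytest.fixture(scope="session")
def cyclohexane_molfile() -> str:
    return molblock("C1CCCCC1")


@pytest.fixture(scope="session")
def benzene(benzene_molfile):
    return cvchem.parse_molfile(benzene_molfile).value


@pytest.fixture(scope="session")
def small_dataset():
    """A deterministic ~150-record dataset exercising every family."""
    return fixtures.gen_dataset(fixtures.FixtureSpec(seed=424242, n_compounds=25))


@pytest.fixture()
def server(small_dataset, tmp_path):
    path = tmp_path / "log.ndjson"
    with open(path, "w", encoding="utf-8") as fh:
        for rec in small_dataset.records:
            fh.write(json.dumps(rec.model_dump(mode="json"), sort_keys=True) + "\n")
    return Server(log_path=str(path))


def login(server: Server, passwords: dict[str, str], role_substring: str) -> tuple[str, str]:
    """(alias, token) for the first fixture account whose alias mentions
    the role."""
    alias = next(a for a in passwords if role_substring in a)
    token = server.request(
        "POST", "/login", {"alias": alias, "password": passwords[alias]}
    ).body["token"]
    return alias, token


def write_log(records: list[store.ChangeRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(mode="json"), sort_keys=True) + "\n")
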