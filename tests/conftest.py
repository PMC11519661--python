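from pathlib import Path

import pytest

from phenograph import datasets

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    return datasets.load_registry()


@pytest.fixture(scope="session")
def sakalava(registry):
    return datasets.load_description("sakalava", registry)


@pytest.fixture(scope="session")
def viettei(registry):
    return datasets.load_description("viettei", registry)


@pytest.fixture(scope="session")
def sakalava_clauses():
    return DATA.joinpath("sakalava_clauses.txt").read_text(encoding="utf-8").splitlines()


@pytest.fixture(scope="session")
def viettei_clauses():
    return DATA.joinpath("viettei_clauses.txt").read_text(encoding="utf-8").splitlines()


@pytest.fixture(scope="session")
def malagasy_key():
    return datasets.load_malagasy_key()


@pytest.fixture(scope="session")
def sakalava_records():
    return datasets.load_materials("sakalava")


@pytest.fixture(scope="session")
def viettei_records():
    return datasets.load_materials("viettei")
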