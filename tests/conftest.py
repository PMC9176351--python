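from __future__ import annotations

import pytest

from cfgmon import annotate_stream, builtin_pools, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def pools():
    return builtin_pools()


@pytest.fixture()
def annotate(catalog):
    """Annotate a list of SMILES strings against the default catalog."""

    def _annotate(smiles_list):
        return annotate_stream(smiles_list, catalog)

    return _annotate


# Small corpus of valid H/C/N/O molecules for language-model fitting.
TINY_CORPUS = [
    "CCO",
    "CCN",
    "CCC",
    "CC(C)=O",
    "c1ccccc1",
    "Nc1ccccc1",
    "CC(=O)C(C)=O",
    "O=C1C=CC(=O)C=C1",
    "CCOC",
    "CNC",
]


@pytest.fixture(scope="session")
def tiny_corpus():
    return list(TINY_CORPUS)
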