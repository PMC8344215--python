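import pytest

from lousemito.fixtures import (
    POLYPLAX_TAXA,
    nonpolyplax_pair_table,
    polyplax_karyotypes,
    polyplax_mrca_variants,
    sucking_lice_mrca,
    sucking_lice_tree,
)


@pytest.fixture(scope="session")
def karyos():
    return polyplax_karyotypes()


@pytest.fixture(scope="session")
def reclinata(karyos):
    return karyos["Polyplax_reclinata"]


@pytest.fixture(scope="session")
def spinulosa(karyos):
    return karyos["Polyplax_spinulosa"]


@pytest.fixture(scope="session")
def asiatica(karyos):
    return karyos["Polyplax_asiatica"]


@pytest.fixture(scope="session")
def mrca_variants():
    return polyplax_mrca_variants()


@pytest.fixture(scope="session")
def anoplura_mrca():
    return sucking_lice_mrca()


@pytest.fixture(scope="session")
def tree():
    return sucking_lice_tree()


@pytest.fixture(scope="session")
def pair_table():
    return nonpolyplax_pair_table()


@pytest.fixture(scope="session")
def ingroup():
    return set(POLYPLAX_TAXA)
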