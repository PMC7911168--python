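import pytest
from hypothesis import settings

import popdiff as P

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: Printed study frequencies for the IND cohort, keyed by variant, as
#: (text value, called chromosomes behind it).  Text form preserves the
#: published number of decimals.
IND_PRINTED = {
    "rs799923": ("0.016", 128),
    "rs16941": ("0.453", 128),
    "rs16942": ("0.453", 128),
    "rs1799966": ("0.453", 128),
    "rs12516": ("0.24", 128),
    "rs799905": ("0.4754", 122),
    "rs1799949": ("0.4531", 128),
    "rs799917": ("0.4841", 126),
    "rs11571769": ("0.1111", 126),
    "rs144848": ("0.5078", 128),
    "rs1799943": ("0.0937", 128),
    "rs11571651": ("0", 128),
    "rs1799944": ("0.1406", 128),
    "rs11571707": ("0.3203", 128),
    "rs766173": ("0.1379", 116),
}


def agrees_with_printed(value: float, printed: str) -> bool:
    """True when ``value`` matches ``printed`` to half a unit in its last digit."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return abs(value - float(printed)) <= 0.5 * 10 ** (-decimals) + 1e-12


@pytest.fixture(scope="session")
def ind_matrix():
    return P.make_ind_fixture()


@pytest.fixture(scope="session")
def manifest():
    return P.load_published_manifest()


@pytest.fixture(scope="session")
def published_freqs(manifest):
    return P.load_published_frequencies(manifest)


@pytest.fixture(scope="session")
def ethnic_counts():
    return P.load_published_ethnic_counts()


@pytest.fixture(scope="session")
def ind_freq_table(ind_matrix):
    return P.frequency_table_from_genotypes(ind_matrix)
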