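import numpy as np
import pytest

from codlipids import study_tables
from codlipids.profiles import FattyAcidProfile


@pytest.fixture(scope="session")
def table1():
    return study_tables.load_table1()


@pytest.fixture(scope="session")
def table2():
    return study_tables.load_table2()


@pytest.fixture(scope="session")
def table3():
    return study_tables.load_table3()


@pytest.fixture(scope="session")
def summaries():
    return study_tables.load_group_summaries()


@pytest.fixture(scope="session")
def group_totals():
    return study_tables.load_group_totals()


@pytest.fixture(scope="session")
def mean_profiles(summaries):
    return {s.origin: s.mean_profile() for s in summaries}


@pytest.fixture
def toy_profile():
    return FattyAcidProfile(
        sample_id="toy",
        origin="Norway",
        composition={"C14:0": 10.0, "C18:1 cis-9": 90.0},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230202)
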