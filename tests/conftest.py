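import numpy as np
import pytest

from smdrank import toy_complex as toy


@pytest.fixture(scope="session")
def table1():
    return toy.load_table("table1")


@pytest.fixture(scope="session")
def table2():
    return toy.load_table("table2")


@pytest.fixture(scope="session")
def table7():
    return toy.load_table("table7")


@pytest.fixture(scope="session")
def fmax_fit(table1, table2):
    from smdrank import affinity_stats as afs

    return afs.gof_suite(afs.fit_ols(table1["fmax_pn"], table2["ki_nm"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
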