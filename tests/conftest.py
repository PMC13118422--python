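import pytest

import carbodose as cd


@pytest.fixture(scope="session")
def pooled_all():
    """(simulation set, per-parameter pooled results) from the packaged
    published study table under the documented reproduction configuration."""
    return cd.pool_study_table(cd.packaged_study_table())


@pytest.fixture(scope="session")
def pset(pooled_all):
    return pooled_all[0]


@pytest.fixture(scope="session")
def pk_params(pset):
    return cd.PKParameters.from_pooled(pset)


@pytest.fixture(scope="session")
def cohort_biased():
    """The packaged reference cohort (published default seed, biased mode)."""
    return cd.default_cohort()


@pytest.fixture(scope="session")
def cohort_consistent():
    return cd.default_cohort(discrepancy=cd.DiscrepancyModel(mode="consistent"))
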