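import pytest

from ombcrosswalk import (
    batch_harmonize,
    build_pooled_fixture,
    default_mapping_table,
    default_taxonomy,
    pooled_schemas,
)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def mapping_table():
    return default_mapping_table()


@pytest.fixture(scope="session")
def pooled_records():
    return build_pooled_fixture(seed=1)


@pytest.fixture(scope="session")
def pooled_allocations(pooled_records, mapping_table):
    return batch_harmonize(pooled_records, pooled_schemas(), mapping_table)
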