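import pytest

from bradyvar import dataset


@pytest.fixture(scope="session")
def curated():
    return dataset.load_curated()


@pytest.fixture(scope="session")
def curated_t3(curated):
    return [r for r in curated if r.table_of_origin == "T3"]


@pytest.fixture(scope="session")
def ledger():
    return dataset.load_screening_ledger()
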