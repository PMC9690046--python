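import pytest

from mitovar.reference import packaged_reference, region_table


@pytest.fixture(scope="session")
def ref():
    return packaged_reference()


@pytest.fixture(scope="session")
def regions():
    return region_table()
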