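import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from ptp1b_qsar import (
    packaged_binding_table,
    packaged_errata,
    packaged_flavonoid_table,
    packaged_reference_splits,
)


@pytest.fixture(scope="session")
def flavonoids():
    """The packaged 46-flavonoid descriptor/activity table."""
    return packaged_flavonoid_table()


@pytest.fixture(scope="session")
def binding_records():
    """The packaged 27-ligand binding-affinity table."""
    return packaged_binding_table()


@pytest.fixture(scope="session")
def reference_splits():
    return packaged_reference_splits()


@pytest.fixture(scope="session")
def errata():
    return packaged_errata()
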