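import numpy as np
import pytest

from conidiokit import CrossCountsTable, default_design, load_f2_counts


@pytest.fixture(scope="session")
def f2_counts() -> CrossCountsTable:
    """The packaged 3-cross F2 phenotype counts table."""
    return load_f2_counts()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220228)
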