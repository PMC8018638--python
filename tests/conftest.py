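import numpy as np
import pytest

from recstress import extract_lower_records, load_steel_data


@pytest.fixture(scope="session")
def steel():
    """The two bundled 20-value steel fatigue-lifetime samples (x, y)."""
    return load_steel_data()


@pytest.fixture(scope="session")
def steel_records(steel):
    x, y = steel
    return extract_lower_records(x), extract_lower_records(y)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
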