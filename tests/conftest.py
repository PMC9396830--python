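import numpy as np
import pytest

from lbpsim import reference
from lbpsim.synthetic_data import make_table1_bundle, make_stress_bundles


@pytest.fixture(scope="session")
def bundle():
    """Default bundle calibrated to the published 2020 margins."""
    return make_table1_bundle(0)


@pytest.fixture(scope="session")
def stress_bundles():
    return {b.name: b for b in make_stress_bundles(0)}


@pytest.fixture(scope="session")
def margins():
    return reference.syl2020_margins()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
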