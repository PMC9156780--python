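import numpy as np
import pytest

from ampledit import make_editing_pool, make_reference
from ampledit.simulate import make_large_deletion_pool

CATEGORY_FRACTIONS = {"WT": 0.36, "Deletion": 0.30, "Insertion": 0.14, "Multiple": 0.20}


@pytest.fixture(scope="session")
def short_ref():
    return make_reference(300, (120, 139), seed=7)


@pytest.fixture(scope="session")
def editing_pool(short_ref):
    return make_editing_pool(short_ref, dict(CATEGORY_FRACTIONS), seed=1)


@pytest.fixture(scope="session")
def long_ref():
    return make_reference(4200, (2059, 2078), seed=11)


@pytest.fixture(scope="session")
def long_pool(long_ref):
    return make_large_deletion_pool(long_ref, (500, 1500, 3900), wt_fraction=0.4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
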